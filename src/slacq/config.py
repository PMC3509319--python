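"""Pipeline configuration: every named constant of the analysis in one place.

Defaults are the analysis' operating points: screen inclusion at E-value
1e-3, curation cut-offs 20/97 percent identity, the 25% alignment gap mask,
the >90%/0.6/0.2 phosphosite criteria, a 19-residue hydropathicity window,
and 1000 bootstrap replicates. Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Section):
    family: str = "slac"
    n_species: int = 10
    birth_rate: float = 1.0
    n_decoys: int = 5
    within_identity: tuple[float, ...] = (78.0, 69.0, 58.0)
    between_identity_close: float = 52.0
    between_identity_far: float = 35.5
    crown_spread: float = 0.2
    dup_rate: float = 0.0
    loss_rate: float = 0.0


class ScreenConfig(_Section):
    evalue_max: float = 1e-3  # at-least-one-motif inclusion threshold
    pseudocount_weight: float = 1.0
    calibration_n_random: int = 1000
    calibration_len_random: int = 400
    seed_rows_per_group: int = 2


class CurationConfig(_Section):
    low: float = 20.0  # pairs below: unrelated, no edge
    high: float = 97.0  # pairs above: duplicates, collapsed
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    max_missing_frac: float = 0.1


class ClusterConfig(_Section):
    n_groups: int = 3
    bootstrap_reps: int = 1000
    block_min_ident_frac: float = 0.5
    block_max_gap_frac: float = 0.5
    block_min_len: int = 5
    zone_window: int = 11
    zone_threshold: float = 0.5


class TracksConfig(_Section):
    kd_window: int = 19
    max_gap_frac: float = 0.25
    tm_score_min: float = 1.0
    tm_min_len: int = 10


class PhosphoConfig(_Section):
    cons_min: float = 0.90
    max_min: float = 0.6
    mean_min: float = 0.2
    mean_over: str = "carriers"
    pfm_halfwidth: int = 4


class PipelineConfig(_Section):
    seed: int = 0
    outdir: str = "slacq_run"
    simulate: SimulateConfig = SimulateConfig()
    screen: ScreenConfig = ScreenConfig()
    curation: CurationConfig = CurationConfig()
    cluster: ClusterConfig = ClusterConfig()
    tracks: TracksConfig = TracksConfig()
    phospho: PhosphoConfig = PhosphoConfig()


def validate_config(data: dict) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a raw config mapping; returns (config, errors).

    All violations are reported, not only the first; range rules beyond the
    schema (fractions in [0, 1], identities in [0, 100], odd KD window) are
    checked here.
    """
    errors: list[str] = []
    try:
        config = PipelineConfig.model_validate(data)
    except ValidationError as exc:
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"])
            errors.append(f"{loc}: {err['msg']}")
        return None, errors

    def frac(name: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            errors.append(f"{name}: {value} outside [0, 1]")

    def pct(name: str, value: float) -> None:
        if not (0.0 <= value <= 100.0):
            errors.append(f"{name}: {value} outside [0, 100]")

    frac("tracks.max_gap_frac", config.tracks.max_gap_frac)
    frac("phospho.cons_min", config.phospho.cons_min)
    frac("phospho.max_min", config.phospho.max_min)
    frac("phospho.mean_min", config.phospho.mean_min)
    frac("cluster.block_min_ident_frac", config.cluster.block_min_ident_frac)
    frac("cluster.block_max_gap_frac", config.cluster.block_max_gap_frac)
    frac("cluster.zone_threshold", config.cluster.zone_threshold)
    pct("curation.low", config.curation.low)
    pct("curation.high", config.curation.high)
    for t in config.simulate.within_identity:
        pct("simulate.within_identity", t)
    if config.tracks.kd_window < 1 or config.tracks.kd_window % 2 == 0:
        errors.append(f"tracks.kd_window: {config.tracks.kd_window} must be odd and >= 1")
    if config.phospho.mean_over not in ("carriers", "all"):
        errors.append(f"phospho.mean_over: {config.phospho.mean_over!r} not in (carriers, all)")
    if config.screen.evalue_max <= 0:
        errors.append(f"screen.evalue_max: {config.screen.evalue_max} must be > 0")
    if config.cluster.bootstrap_reps < 1:
        errors.append("cluster.bootstrap_reps: must be >= 1")
    if errors:
        return None, errors
    return config, []


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; missing path means all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    config, errors = validate_config(raw)
    if config is None:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return config
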