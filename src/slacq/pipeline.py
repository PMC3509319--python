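"""Stage orchestration: pure functions of (inputs, config, seed) with a
machine-readable run manifest.

Each stage reads its declared inputs from the working directory, writes TSV
/ FASTA / Newick outputs, and records in/out counts in ``manifest.json`` so
a run can be audited and re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .curation import ScoringConfig, curate, write_group_report
from .grouping import (
    bootstrap_support,
    conserved_blocks,
    conservation_zones,
    cut_to_clusters,
    group_identity_stats,
    identity_distance_matrix,
    upgma,
    write_block_report,
    write_distance_matrix,
    write_zone_report,
)
from .hmm import build_profile, calibrate_evalue, screen_proteome, write_hits_tsv
from .phospho import SurrogatePWMScorer, pfm_window, screen_phosphosites, write_pfm, write_site_reports
from .reconcile import annotate_duplication_history, lca_reconcile, write_reconciliation_report
from .sequences import read_alignment_fasta, read_fasta, read_species_map, write_fasta
from .synth import FamilyConfig, make_benchmark, motif_seed_alignment, write_benchmark
from .tracks import call_tm_segments, clade_average, kd_hydropathicity, project_tracks
from .trees import write_newick

log = logging.getLogger("slacq")

STAGES = ["simulate", "screen", "curate", "cluster", "reconcile", "tracks", "phospho"]


class StageError(RuntimeError):
    pass


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _read_groups(path: Path) -> dict[str, str]:
    groups = {}
    for line in path.read_text().splitlines()[1:]:
        sid, g = line.split("\t")
        groups[sid] = g
    return groups


def _bundle_dir(workdir: Path) -> Path:
    bundle = workdir / "bundle"
    if not bundle.is_dir():
        raise StageError(f"missing input: {bundle} (run the simulate stage first)")
    return bundle


def run_stage(name: str, config: PipelineConfig, workdir: str | Path) -> dict:
    """Run one pipeline stage; returns its manifest entry."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    fn = {
        "simulate": _stage_simulate,
        "screen": _stage_screen,
        "curate": _stage_curate,
        "cluster": _stage_cluster,
        "reconcile": _stage_reconcile,
        "tracks": _stage_tracks,
        "phospho": _stage_phospho,
    }.get(name)
    if fn is None:
        raise StageError(f"unknown stage {name!r}; stages are {STAGES}")
    log.info("stage %s: start", name)
    entry = fn(config, workdir)
    entry["stage"] = name
    _update_manifest(workdir, config, entry)
    log.info("stage %s: done %s", name, {k: v for k, v in entry.items() if k != "stage"})
    return entry


def run_all(config: PipelineConfig, workdir: str | Path) -> list[dict]:
    return [run_stage(name, config, workdir) for name in STAGES]


def _update_manifest(workdir: Path, config: PipelineConfig, entry: dict) -> None:
    path = workdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "tool": "slacq",
        "version": __version__,
        "config": config.model_dump(),
        "seed": config.seed,
        "stages": {},
    }
    manifest["stages"][entry["stage"]] = {k: v for k, v in entry.items() if k != "stage"}
    path.write_text(json.dumps(manifest, sort_keys=True, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, workdir: Path) -> dict:
    fam = FamilyConfig(seed=config.seed, **config.simulate.model_dump())
    bundle = make_benchmark(fam)
    outdir = write_benchmark(bundle, workdir / "bundle")
    return {
        "n_members": len(bundle.sequences),
        "n_decoys": len(bundle.decoys),
        "n_groups": len(set(bundle.groups.values())),
        "bundle_hash": _hash_file(outdir / "manifest.json"),
    }


def _stage_screen(config: PipelineConfig, workdir: Path) -> dict:
    bundle_dir = _bundle_dir(workdir)
    fam = FamilyConfig(seed=config.seed, **config.simulate.model_dump())
    bundle = make_benchmark(fam)  # deterministic regeneration, same manifest
    proteome = read_fasta(bundle_dir / "sequences.fasta")
    models = []
    for i, motif in enumerate(sorted(bundle.motif_regions)):
        seed_aln = motif_seed_alignment(bundle, motif,
                                        config.screen.seed_rows_per_group)
        model = build_profile(seed_aln, config.screen.pseudocount_weight,
                              motif_id=motif)
        calibrate_evalue(model, config.screen.calibration_n_random,
                         config.screen.calibration_len_random,
                         seed=config.seed + i + 1)
        models.append(model)
    result = screen_proteome(models, proteome, config.screen.evalue_max)
    write_hits_tsv(result, workdir / "screen_hits.tsv")
    kept = [s for s in proteome if s.id in set(result.kept)]
    write_fasta(kept, workdir / "screen_kept.fasta")
    return {
        "n_motifs": len(models),
        "n_screened": len(proteome),
        "n_kept": len(kept),
    }


def _stage_curate(config: PipelineConfig, workdir: Path) -> dict:
    kept_path = workdir / "screen_kept.fasta"
    if not kept_path.exists():
        raise StageError(f"missing input: {kept_path} (run the screen stage first)")
    candidates = read_fasta(kept_path)
    groups_truth = _read_groups(_bundle_dir(workdir) / "groups.tsv")
    # reference channels: the first member of each group, by id order
    refs_ids = sorted({g: min(s for s in groups_truth if groups_truth[s] == g)
                       for g in set(groups_truth.values())}.values())
    refs = [c for c in candidates if c.id in refs_ids]
    scoring = ScoringConfig(matrix=config.curation.matrix,
                            gap_open=config.curation.gap_open,
                            gap_extend=config.curation.gap_extend)
    selected, graph, all_groups = curate(
        candidates, refs, low=config.curation.low, high=config.curation.high,
        scoring_config=scoring,
    )
    write_group_report(all_groups, selected, workdir / "curation_groups.tsv")
    write_fasta([c for c in candidates if c.id in set(selected.members)],
                workdir / "curated.fasta")
    return {
        "n_candidates": len(candidates),
        "n_duplicates_removed": len(graph.removed_as_duplicate),
        "n_groups": len(all_groups),
        "n_selected": len(selected.members),
    }


def _stage_cluster(config: PipelineConfig, workdir: Path) -> dict:
    bundle_dir = _bundle_dir(workdir)
    aln = read_alignment_fasta(bundle_dir / "true_alignment.fasta")
    D = identity_distance_matrix(aln)
    write_distance_matrix(D, workdir / "distances.tsv")
    tree = bootstrap_support(aln, n_reps=config.cluster.bootstrap_reps,
                             seed=config.seed)
    (workdir / "upgma.nwk").write_text(write_newick(tree, supports=True))
    assignment = cut_to_clusters(tree, config.cluster.n_groups)
    with open(workdir / "upgma_groups.tsv", "w") as fh:
        fh.write("seq_id\tcluster\n")
        for sid in sorted(assignment):
            fh.write(f"{sid}\tc{assignment[sid]}\n")
    groups_truth = _read_groups(bundle_dir / "groups.tsv")
    stats = group_identity_stats(aln, groups_truth)
    with open(workdir / "group_identity_stats.tsv", "w") as fh:
        fh.write("scope\tgroups\tmean\tsd\tmin\tmax\tn_pairs\n")
        for g, s in sorted(stats.within.items()):
            if s is not None:
                fh.write(f"within\t{g}\t{s.mean:.2f}\t{s.sd:.2f}\t{s.min:.2f}"
                         f"\t{s.max:.2f}\t{s.n_pairs}\n")
        for (ga, gb), s in sorted(stats.between.items()):
            fh.write(f"between\t{ga}|{gb}\t{s.mean:.2f}\t{s.sd:.2f}\t{s.min:.2f}"
                     f"\t{s.max:.2f}\t{s.n_pairs}\n")
    blocks = conserved_blocks(aln, config.cluster.block_min_ident_frac,
                              config.cluster.block_min_len,
                              config.cluster.block_max_gap_frac)
    write_block_report(blocks, workdir / "robust_blocks.tsv")
    zones = conservation_zones(aln, config.cluster.zone_window,
                               config.cluster.zone_threshold)
    write_zone_report(zones, workdir / "conservation_zones.tsv")
    return {
        "n_taxa": aln.nrow,
        "n_clusters": config.cluster.n_groups,
        "n_blocks": len(blocks),
        "n_zones": len(zones),
    }


def _stage_reconcile(config: PipelineConfig, workdir: Path) -> dict:
    from .trees import read_newick

    bundle_dir = _bundle_dir(workdir)
    gene = read_newick((bundle_dir / "gene_tree.nwk").read_text())
    species = read_newick((bundle_dir / "species_tree.nwk").read_text())
    species_map = read_species_map(bundle_dir / "species_map.tsv")
    rec = lca_reconcile(gene, species, species_map)
    write_reconciliation_report(rec, workdir / "reconciliation.tsv")
    groups_truth = _read_groups(bundle_dir / "groups.tsv")
    events = annotate_duplication_history(rec, groups_truth)
    with open(workdir / "duplication_events.tsv", "w") as fh:
        fh.write("species_node\tside_a\tside_b\n")
        for e in events:
            fh.write(f"{e.species_node}\t{','.join(e.side_a)}\t{','.join(e.side_b)}\n")
    return {"n_duplications": rec.duplication_count, "n_losses": rec.loss_count}


def _stage_tracks(config: PipelineConfig, workdir: Path) -> dict:
    from .tracks import write_profile_tsv

    bundle_dir = _bundle_dir(workdir)
    aln = read_alignment_fasta(bundle_dir / "true_alignment.fasta")
    groups = _read_groups(bundle_dir / "groups.tsv")
    tracks = [kd_hydropathicity(aln.ungapped(sid), config.tracks.kd_window)
              for sid in aln.ids]
    col_tracks = project_tracks(tracks, aln)
    profiles = clade_average(col_tracks, groups, config.tracks.max_gap_frac)
    write_profile_tsv(profiles, workdir / "kd_profiles.tsv")
    segments = call_tm_segments(profiles["all"], config.tracks.tm_score_min,
                                config.tracks.tm_min_len)
    with open(workdir / "tm_segments.tsv", "w") as fh:
        fh.write("start_col\tend_col\tmean_hydropathicity\tclade\n")
        for s in segments:
            fh.write(f"{s.start_col}\t{s.end_col}\t{s.mean_hydropathicity:.3f}"
                     f"\t{s.clade}\n")
    return {"n_sequences": aln.nrow, "n_tm_segments": len(segments)}


def _stage_phospho(config: PipelineConfig, workdir: Path) -> dict:
    bundle_dir = _bundle_dir(workdir)
    aln = read_alignment_fasta(bundle_dir / "true_alignment.fasta")
    groups = _read_groups(bundle_dir / "groups.tsv")
    scorer = SurrogatePWMScorer()
    reports, _tracks = screen_phosphosites(
        aln, groups, scorer,
        cons_min=config.phospho.cons_min, max_min=config.phospho.max_min,
        mean_min=config.phospho.mean_min, mean_over=config.phospho.mean_over,
    )
    write_site_reports(reports, workdir / "phosphosites.tsv")
    pfm_dir = workdir / "pfm"
    pfm_dir.mkdir(exist_ok=True)
    for r in reports:
        members = sorted(m for m, g in groups.items() if g == r.group)
        half = min(config.phospho.pfm_halfwidth, r.column - 1, aln.ncol - r.column)
        pfm = pfm_window(aln, r.column, half, members, group=r.group)
        write_pfm(pfm, pfm_dir / f"{r.group}_col{r.column}.tsv")
    return {"n_sites": len(reports)}
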