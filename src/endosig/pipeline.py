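"""Pipeline orchestration: one configured, seeded, reproducible run.

Binds the stages together in dependency order — synthetic data generation,
differential binding, region-set algebra, overlap enrichment, motif
enrichment, expression analysis and copy-number segmentation — writing
every artifact plus an echo of the fully resolved configuration and a log
of the seed into one output directory. Identical configuration and seed
give byte-identical outputs.
"""
from __future__ import annotations

import copy
import json
from pathlib import Path

import pandas as pd
import yaml

from . import cnv, diffbind, expression, io, motifs, overlap, region_sets, simulate

__all__ = ["default_config", "resolve_config", "run_pipeline"]

ALL_STAGES = [
    "simulate",
    "diffbind",
    "region_sets",
    "overlap",
    "motif",
    "expression",
    "cnv",
]

# downstream stage -> required upstream stages
_DEPENDENCIES = {
    "diffbind": ["simulate"],
    "region_sets": ["diffbind"],
    "overlap": ["region_sets"],
    "motif": ["simulate"],
    "expression": ["simulate"],
    "cnv": ["simulate"],
}


def default_config() -> dict:
    """The full default configuration (small synthetic problem sizes)."""
    return {
        "seed": simulate.DEFAULT_SEED,
        "out_dir": "endosig_run",
        "log_level": "INFO",
        "stages": list(ALL_STAGES),
        "simulate": {
            "chip": {
                "n_regions": 500,
                "design": ["ctrl", "ctrl", "ctrl", "akt", "akt", "akt"],
                "dbr_fraction": 0.1,
                "lfc": 2.0,
                "dispersion": 0.1,
                "lib_sizes": [1_000_000] * 6,
            },
            "expression": {
                "n_genes": 1000,
                "groups": ["ctrl", "ctrl", "ctrl", "akt", "akt", "akt"],
                "de_fraction": 0.1,
                "lfc": 3.0,
                "noise_sd": 0.3,
            },
            "coverage": {
                "n_bins": 300,
                "segments": [[100, 200, 1.0]],
                "depth": 500.0,
                "noise_sd": 0.0,
            },
            "sequences": {
                "n_fg": 100,
                "n_bg": 100,
                "length": 200,
                "background_freqs": [0.25, 0.25, 0.25, 0.25],
                "plant_rate_fg": 0.3,
                "plant_rate_bg": 0.02,
            },
        },
        "diffbind": {
            "factor": "cell_type",
            "lfc_min": 1.5,
            "fdr_max": 0.01,
            "logcpm_min": -3.0,
            "prior_df": 10.0,
        },
        "region_sets": {},
        "overlap": {"n_control": 10_000, "log_base": "e"},
        "motif": {"score_threshold_fraction": 0.8},
        "expression_stage": {
            "lfc_threshold": 1.0,
            "p_threshold": 0.05,
            "pseudocount": 1.0,
            "linkage": "complete",
        },
        "cnv": {
            "alpha": 0.01,
            "n_permutations": 1000,
            "min_width": 2,
            "sd_multiple": 3.0,
        },
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown configuration key {where!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = copy.deepcopy(val)
    return out


def resolve_config(config: dict | None = None) -> dict:
    """Merge a partial configuration over the defaults; unknown keys are
    rejected."""
    cfg = _merge(default_config(), config or {})
    unknown = set(cfg["stages"]) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    selected = set(cfg["stages"])
    for stage in cfg["stages"]:
        for dep in _DEPENDENCIES.get(stage, []):
            if dep not in selected:
                raise ValueError(
                    f"stage {stage!r} requires upstream stage {dep!r} to be selected"
                )
    return cfg


def run_pipeline(config: dict | None = None) -> Path:
    """Execute the selected stages end to end; returns the artifact
    directory."""
    cfg = resolve_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log_lines = [f"seed={seed}", f"stages={','.join(cfg['stages'])}"]

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    stages = cfg["stages"]
    artifacts: dict[str, object] = {}

    if "simulate" in stages:
        sim = cfg["simulate"]
        rc, chip_truth = simulate.simulate_chip_counts(seed=seed, **sim["chip"])
        io.write_region_counts(rc, out / "chip_counts.tsv", out / "sample_sheet.tsv")
        io.write_bed(rc.regions, out / "regions.bed")
        chip_truth.to_tsv(str(out / "chip_truth.tsv"))
        artifacts["rc"] = rc

        expr, expr_truth = simulate.simulate_expression(seed=seed + 1, **sim["expression"])
        io.write_expression(expr, out / "fpkm.tsv", out / "expr_groups.tsv")
        expr_truth.to_tsv(str(out / "expr_truth.tsv"))
        artifacts["expr"] = expr

        segs = [tuple(s) for s in sim["coverage"]["segments"]]
        cov_args = {**sim["coverage"], "segments": segs}
        (sam, ref), cov_truth = simulate.simulate_binned_coverage(
            seed=seed + 2, **cov_args
        )
        cov_truth.to_tsv(str(out / "coverage_truth.tsv"))
        artifacts["coverage"] = (sam, ref)

        pwms = motifs.example_pwms()
        seqs, seq_truth = simulate.simulate_sequences(
            seed=seed + 3, pwm=pwms[0], **sim["sequences"]
        )
        io.write_fasta(
            {f"fg_{i:04d}": s for i, s in enumerate(seqs["fg"])}, out / "fg.fasta"
        )
        io.write_fasta(
            {f"bg_{i:04d}": s for i, s in enumerate(seqs["bg"])}, out / "bg.fasta"
        )
        seq_truth.to_tsv(str(out / "sequence_truth.tsv"))
        artifacts["seqs"] = seqs
        artifacts["pwms"] = pwms
        log_lines.append("simulate: ok")

    if "diffbind" in stages:
        rc = artifacts["rc"]
        db = cfg["diffbind"]
        result = diffbind.differential_binding(
            rc,
            factor=db["factor"],
            lfc_min=db["lfc_min"],
            fdr_max=db["fdr_max"],
            logcpm_min=db["logcpm_min"],
            prior_df=db["prior_df"],
        )
        io.write_table(result, out / "dbr_results.tsv")
        artifacts["dbr"] = result
        log_lines.append(f"diffbind: {int((result['call'] != 'ns').sum())} DBRs")

    if "region_sets" in stages:
        up, down = region_sets.differential_sets(artifacts["dbr"])
        io.write_bed(up, out / "dbr_up.bed")
        io.write_bed(down, out / "dbr_down.bed")
        artifacts["up"], artifacts["down"] = up, down
        log_lines.append(f"region_sets: up={len(up)} down={len(down)}")

    if "overlap" in stages:
        rc = artifacts["rc"]
        ov = cfg["overlap"]
        genome_end = max(iv.end for iv in rc.regions)
        chrom_sizes = {"chr1": genome_end + 10_000}
        query = artifacts["up"] if len(artifacts["up"]) else artifacts["down"]
        rows = []
        if len(query):
            track = rc.regions  # candidate regions as a trivial annotation
            control = overlap.sample_matched_control(
                query, chrom_sizes, int(ov["n_control"]), seed=seed + 4
            )
            enr = overlap.overlap_log_odds(
                query, track, control, log_base=ov["log_base"], seed=seed + 4
            )
            rows.append(
                {
                    "query": query.name,
                    "track": "candidate_regions",
                    "a": enr.a,
                    "b": enr.b,
                    "c": enr.c,
                    "d": enr.d,
                    "log_odds": enr.log_odds,
                }
            )
        io.write_table(
            pd.DataFrame(
                rows, columns=["query", "track", "a", "b", "c", "d", "log_odds"]
            ),
            out / "overlap_enrichment.tsv",
        )
        log_lines.append(f"overlap: {len(rows)} enrichments")

    if "motif" in stages:
        seqs, pwms = artifacts["seqs"], artifacts["pwms"]
        table = motifs.motif_enrichment(
            seqs["fg"],
            seqs["bg"],
            pwms,
            score_threshold_fraction=cfg["motif"]["score_threshold_fraction"],
        )
        io.write_table(table, out / "motif_enrichment.tsv")
        log_lines.append(f"motif: top={table.iloc[0]['pwm']}")

    if "expression" in stages:
        expr = artifacts["expr"]
        ex = cfg["expression_stage"]
        groups = sorted(expr.groups.unique())
        de = expression.de_genes(
            expr,
            groups[0],
            groups[1],
            lfc_threshold=ex["lfc_threshold"],
            p_threshold=ex["p_threshold"],
            pseudocount=ex["pseudocount"],
        )
        io.write_table(de.reset_index(), out / "de_genes.tsv")
        dist = expression.correlation_distance_matrix(expr)
        io.write_table(dist.rename_axis("sample").reset_index(), out / "distance_matrix.tsv")
        dend = expression.hierarchical_cluster(dist, linkage=ex["linkage"])
        (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        ref_group = groups[-1]
        ref_ids = expr.group_samples(ref_group)
        dref = expression.distance_to_reference_average(expr, ref_ids)
        io.write_table(dref.rename_axis("sample").reset_index(), out / "distance_to_reference.tsv")
        log_lines.append(f"expression: {int(de['de_flag'].sum())} DE genes")

    if "cnv" in stages:
        sam, ref = artifacts["coverage"]
        cn = cfg["cnv"]
        ratios = cnv.normalize_log2_ratio(sam, ref)
        profile = cnv.cbs_segment(
            ratios,
            alpha=cn["alpha"],
            n_permutations=int(cn["n_permutations"]),
            min_width=int(cn["min_width"]),
            seed=seed + 5,
            bin_width=sam.bin_width,
        )
        profile = cnv.call_splits(profile, sd_multiple=cn["sd_multiple"])
        segs = profile.segments.copy()
        segs["start"] = segs["start_bin"] * profile.bin_width
        segs["end"] = segs["end_bin"] * profile.bin_width
        io.write_table(segs, out / "cnv_segments.tsv")
        with open(out / "cnv_ratios.bedgraph", "w") as fh:
            for chrom in sorted(ratios):
                for b, r in enumerate(ratios[chrom]):
                    fh.write(
                        f"{chrom}\t{b * profile.bin_width}\t{(b + 1) * profile.bin_width}\t{r:.6f}\n"
                    )
        log_lines.append(
            f"cnv: {len(segs)} segments, {int(segs['split_call'].sum())} split calls"
        )

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(out / "run_meta.json", "w") as fh:
        json.dump({"seed": seed, "stages": stages}, fh, sort_keys=True)
    return out
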