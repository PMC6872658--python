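"""End-to-end pipeline: abundance table -> RA -> statistics -> report bundle."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .io import RunConfig, read_abundance_table, write_ra_matrix
from .quantify import (
    AbundanceMatrix,
    HPTMKey,
    enumerate_keys,
    merge_keys,
    quantify_clipping,
    ra_matrix,
)
from .simulate import default_simulation_config, simulate_ra_dataset
from .stats import call_markers, pairwise_passage_tests, pca_scores

__all__ = ["run_pipeline", "apply_standard_merges", "k36_k37_merge_rules", "h3_variant_merge_rules"]

logger = logging.getLogger(__name__)


def k36_k37_merge_rules(ra):
    """Rules folding same-pool K36/K37 neighbours into K36/37 keys."""
    by_vg_mod: dict[tuple[str, str], list[HPTMKey]] = {}
    for k in ra.key_list():
        if not k.clipped and k.residue in ("K36", "K37"):
            by_vg_mod.setdefault((k.variant_group, k.mod), []).append(k)
    return [
        (HPTMKey(vg, "K36/37", mod), members)
        for (vg, mod), members in sorted(by_vg_mod.items())
    ]


def h3_variant_merge_rules(ra):
    """Rules folding H3.1/H3.2 and H3.3 keys into family-level H3 keys."""
    by_res_mod: dict[tuple[str, str], list[HPTMKey]] = {}
    for k in ra.key_list():
        if not k.clipped and k.variant_group in ("H31/H32", "H33", "H31", "H32"):
            by_res_mod.setdefault((k.residue, k.mod), []).append(k)
    return [
        (HPTMKey("H3", res, mod), members)
        for (res, mod), members in sorted(by_res_mod.items())
    ]


def apply_standard_merges(ra, merge_h3_variants: bool, merge_k36_k37: bool):
    """Apply intensity-level K36/37 and/or H3-variant merging in sequence.

    Residue merging runs first so that variant merging then folds the
    already-harmonized residue labels across variant groups.
    """
    if merge_k36_k37:
        rules = k36_k37_merge_rules(ra)
        if rules:
            ra = merge_keys(ra, rules)
    if merge_h3_variants:
        rules = h3_variant_merge_rules(ra)
        if rules:
            ra = merge_keys(ra, rules)
    return ra


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute quantify-ra -> stats (-> merge) and write the report bundle.

    Inputs come from ``config.abundance_table`` or, when none is given, from
    the default synthetic study design seeded by ``config.seed``.  Outputs:
    RA matrix, marker table, pairwise p-value tables, PCA scores, clipping
    RA, the echoed config and a machine-readable manifest.  Reruns with the
    same config and seed produce identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.abundance_table:
            matrix = read_abundance_table(config.abundance_table, config.dialect)
            truth = None
        else:
            sim = default_simulation_config(seed=config.seed)
            sim.passages = config.passages
            sim.replicates = config.replicates
            matrix, truth = simulate_ra_dataset(sim)
        if matrix.values.empty:
            raise ValueError("abundance table has no rows")

        stage = "quantify-ra"
        keys = enumerate_keys(matrix)
        ra = ra_matrix(matrix, keys)
        if config.merge_h3_variants or config.merge_k36_k37:
            stage = "merge-keys"
            ra = apply_standard_merges(
                ra, config.merge_h3_variants, config.merge_k36_k37
            )

        stage = "stats"
        groups = matrix.sample_passages()
        markers = call_markers(
            ra.values,
            groups,
            alpha_timecourse=config.alpha_timecourse,
            alpha_endpoint=config.alpha_endpoint,
            start=config.endpoint_start,
            end=config.endpoint_end,
            equal_var=config.equal_var,
        )
        pairwise = {
            label: pairwise_passage_tests(
                row.to_numpy(), [groups[c] for c in ra.values.columns],
                equal_var=config.equal_var, order=list(config.passages),
            )
            for label, row in ra.values.iterrows()
        }
        scores, explained = pca_scores(ra.values.T.dropna(axis=1, how="all"))
        clipping = quantify_clipping(matrix, clip_site=27)

        stage = "write"
        write_ra_matrix(ra, outdir / "ra_matrix.tsv")
        markers.to_csv(outdir / "marker_table.tsv", sep="\t")
        long_pairwise = pd.concat(
            {k: v for k, v in pairwise.items()}, names=["hptm", "passage"]
        )
        long_pairwise.to_csv(outdir / "pairwise_pvalues.tsv", sep="\t")
        scores.assign(passage=[groups[s] for s in scores.index]).to_csv(
            outdir / "pca_scores.tsv", sep="\t"
        )
        clipping.rename("cH3K27_RA").to_csv(outdir / "clipping_ra.tsv", sep="\t")
        with open(outdir / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        if truth is not None:
            truth.to_json(outdir / "ground_truth.json")

        manifest = {
            "package": "hptmkit",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_peptidoforms": int(matrix.values.shape[0]),
            "n_samples": int(matrix.values.shape[1]),
            "n_keys": int(ra.values.shape[0]),
            "n_markers": int(markers["marker"].sum()),
            "n_time_significant": int(markers["time_significant"].sum()),
            "pca_explained_variance": [float(x) for x in explained[:5]],
            "outputs": sorted(
                p.name for p in outdir.iterdir() if p.name != "manifest.json"
            ),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
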