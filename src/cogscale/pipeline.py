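"""End-to-end orchestration: counts -> fits -> breakpoints -> Z -> null -> phylo.

A run is driven by a flat TOML config (or a PipelineConfig built in code)
and writes plain TSV/JSON outputs plus a manifest that echoes the config,
seeds and row counts, so a run can be reproduced byte-for-byte from its
manifest.  Every stochastic stage draws its seed deterministically from the
master seed and the stage name.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from cogscale import __version__
from cogscale.annotations import (
    CategoryCountMatrix,
    build_count_matrix,
    matrix_to_records,
    parse_annotation_table,
    parse_taxon_map,
)
from cogscale.breakpoints import select_model
from cogscale.errors import (
    CogScaleError,
    DegenerateDesignError,
    InsufficientDataError,
    ValidationError,
)
from cogscale.groups import breakpoint_spans, fit_groups, z_table
from cogscale.nullmodel import null_distribution, null_summary_table
from cogscale.phylo import (
    distance_divergence_association,
    exponent_divergence,
    patristic_phylum_matrix,
)
from cogscale.powerlaw import bin_points, make_fit_input, ols_fit
from cogscale.simulate import (
    BreakpointLaw,
    PhylumSpec,
    ScalingLaw,
    SimulationSpec,
    simulate_matrix,
    write_truth_json,
)

logger = logging.getLogger(__name__)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    # exactly one of (annotations+taxon_map) or simulate must be set
    annotations: str | None = None
    taxon_map: str | None = None
    trees: list[str] = field(default_factory=list)
    simulate: dict | None = None
    zero_policy: str = "drop"
    n_bins: int = 20
    binned: bool = False
    threshold: float = 0.05
    min_segment: int | None = None
    z_mode: str = "as_printed"
    n_perm: int = 0
    seed: int = 0
    outdir: str = "cogscale_out"

    def __post_init__(self) -> None:
        real = self.annotations is not None
        if real == (self.simulate is not None):
            raise ValidationError(
                "config must set exactly one of annotation inputs or a simulation spec"
            )
        if real and self.taxon_map is None:
            raise ValidationError("annotation input requires a taxon_map")
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("threshold must be in (0, 1)")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(**raw)


def _law_from_dict(d: dict):
    kind = d.get("kind", "single")
    if kind == "single":
        return ScalingLaw(d["exponent"], d.get("log10_norm", 0.0), d.get("noise_sd", 0.0))
    if kind == "breakpoint":
        small = ScalingLaw(
            d["exponent_small"], d.get("log10_norm", 0.0), d.get("noise_sd", 0.0)
        )
        return BreakpointLaw(small, d["slope_large"], d["break_x"])
    raise ValidationError(f"unknown law kind {kind!r}")


def spec_from_dict(d: dict, seed: int) -> SimulationSpec:
    """Build a SimulationSpec from a flat config mapping."""
    phyla = None
    if d.get("phyla"):
        phyla = tuple(
            PhylumSpec(p["name"], p["fraction"], p.get("exponent_offsets", {}))
            for p in d["phyla"]
        )
    return SimulationSpec(
        n_organisms=d["n_organisms"],
        total_range=(d["total_min"], d["total_max"]),
        laws={c: _law_from_dict(ld) for c, ld in d["laws"].items()},
        phyla=phyla,
        domain_name=d.get("domain_name", "Bacteria"),
        filler_category=d.get("filler_category"),
        seed=d.get("seed", seed),
    )


def fit_table(
    matrix: CategoryCountMatrix,
    *,
    zero_policy: str = "drop",
    binned: bool = False,
    n_bins: int = 20,
    categories=None,
) -> pd.DataFrame:
    """Whole-matrix fit per category (the domain-level Table-1 analogue)."""
    rows = []
    for cat in categories or matrix.categories:
        row = {"category": cat, "binned": binned}
        try:
            inp = make_fit_input(matrix, cat, zero_policy=zero_policy)
            if binned:
                inp = bin_points(inp, n_bins=n_bins)
            fit = ols_fit(inp)
        except (InsufficientDataError, DegenerateDesignError) as err:
            row.update(
                n=np.nan, n_dropped_zero=np.nan, slope=np.nan, slope_ci95=np.nan,
                slope_se=np.nan, intercept=np.nan, intercept_ci95=np.nan,
                rss=np.nan, r=np.nan, na_reason=type(err).__name__,
            )
        else:
            row.update(
                n=fit.n, n_dropped_zero=inp.n_dropped_zero, slope=fit.slope,
                slope_ci95=fit.slope_ci95, slope_se=fit.slope_se,
                intercept=fit.intercept, intercept_ci95=fit.intercept_ci95,
                rss=fit.rss, r=fit.r, na_reason="",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def model_selection_table(
    matrix: CategoryCountMatrix,
    *,
    level: str = "domain",
    threshold: float = 0.05,
    min_segment: int | None = None,
    zero_policy: str = "drop",
) -> tuple[pd.DataFrame, dict]:
    """Single-vs-segmented selection per (group, category).

    Returns the long-form table and a {(group, category): ScalingModel}
    mapping for downstream span analysis.
    """
    labels = matrix.groups(level)
    rows, models = [], {}
    for group in sorted(labels.dropna().unique()):
        members = labels.index[labels == group]
        for cat in matrix.categories:
            base = {"group": group, "category": cat}
            try:
                inp = make_fit_input(
                    matrix, cat, selector=members,
                    zero_policy=zero_policy, label_group=group,
                )
                model = select_model(inp, threshold=threshold, min_segment=min_segment)
            except (InsufficientDataError, DegenerateDesignError) as err:
                rows.append({**base, "kind": "NA", "na_reason": type(err).__name__})
                continue
            models[(group, cat)] = model
            seg = model.segmented
            rows.append(
                {
                    **base,
                    "kind": model.kind,
                    "rss_single": model.single.rss,
                    "rss_segmented": seg.rss if seg else np.nan,
                    "rss_ratio": model.rss_ratio,
                    "break_x_log10": seg.break_x if seg else np.nan,
                    "break_percentile": seg.break_percentile if seg else np.nan,
                    "break_ci95": seg.break_ci95 if seg else np.nan,
                    "slope1": seg.slope1 if seg else np.nan,
                    "slope1_ci95": seg.slope1_ci95 if seg else np.nan,
                    "slope2": seg.slope2 if seg else np.nan,
                    "slope2_ci95": seg.slope2_ci95 if seg else np.nan,
                    "single_slope": model.single.slope,
                    "single_slope_ci95": model.single.slope_ci95,
                    "na_reason": "",
                    "break_ci_method": "muggeo_se" if seg else "",
                }
            )
    return pd.DataFrame(rows), models


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the output bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Stage failures abort with the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
    }
    stage = "input"
    try:
        truth = None
        if config.simulate is not None:
            spec = spec_from_dict(config.simulate, stage_seed(config.seed, "simulate"))
            matrix, truth = simulate_matrix(spec)
            write_truth_json(truth, out / "truth.json")
        else:
            parsed = parse_annotation_table(config.annotations)
            taxon = parse_taxon_map(config.taxon_map)
            matrix = build_count_matrix(parsed.records, taxon)
            manifest["stages"]["input"] = {"n_skipped": parsed.n_skipped}
        matrix.to_tsv(out / "count_matrix.tsv")
        manifest["stages"]["count_matrix"] = {
            "n_organisms": len(matrix.organisms),
            "n_categories": len(matrix.categories),
        }

        stage = "fits"
        domain_fits = fit_groups(matrix, "domain", zero_policy=config.zero_policy)
        phylum_fits = fit_groups(matrix, "phylum", zero_policy=config.zero_policy)
        domain_fits.to_csv(out / "fits_domain.tsv", sep="\t", index=False)
        phylum_fits.to_csv(out / "fits_phylum.tsv", sep="\t", index=False)
        if config.binned:
            fit_table(
                matrix, zero_policy=config.zero_policy, binned=True,
                n_bins=config.n_bins,
            ).to_csv(out / "fits_binned.tsv", sep="\t", index=False)
        manifest["stages"]["fits"] = {
            "domain_rows": len(domain_fits), "phylum_rows": len(phylum_fits)
        }

        stage = "breakpoints"
        bp_table, models = model_selection_table(
            matrix, level="domain", threshold=config.threshold,
            min_segment=config.min_segment, zero_policy=config.zero_policy,
        )
        bp_table.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
        manifest["stages"]["breakpoints"] = {
            "segmented": int((bp_table["kind"] == "segmented").sum())
        }

        stage = "zscores"
        dmap = {
            p: matrix.taxon.loc[matrix.groups("phylum") == p, "domain"].iloc[0]
            for p in matrix.groups("phylum").dropna().unique()
        }
        for mode in ("as_printed", "sum_of_squares"):
            zt = z_table(phylum_fits, domain_fits, mode=mode, group_to_domain=dmap)
            zt.to_csv(out / f"zscores_{mode}.tsv", sep="\t", index=False)
        manifest["stages"]["zscores"] = {"modes": ["as_printed", "sum_of_squares"]}

        stage = "breakpoint_spans"
        for domain in sorted(set(dmap.values())):
            dom_models = {c: m for (g, c), m in models.items() if g == domain}
            sub = matrix.subset(
                matrix.taxon.index[matrix.taxon["domain"] == domain]
            )
            spans = breakpoint_spans(sub, dom_models, level="phylum")
            spans.to_csv(out / f"breakpoint_spans_{domain}.tsv", sep="\t", index=False)

        stage = "null"
        if config.n_perm > 0:
            records = matrix_to_records(matrix)
            results = [
                null_distribution(
                    records, cat, config.n_perm,
                    stage_seed(config.seed, f"null:{cat}"),
                    taxon_map=matrix.taxon, zero_policy=config.zero_policy,
                )
                for cat in matrix.categories
            ]
            null_summary_table(results).to_csv(
                out / "null_summary.tsv", sep="\t", index=False
            )
            manifest["stages"]["null"] = {"n_perm": config.n_perm}

        stage = "phylo"
        if config.trees:
            assoc_rows = []
            slopes_by_cat = {
                cat: dict(
                    phylum_fits[phylum_fits["category"] == cat][["group", "slope"]]
                    .dropna()
                    .itertuples(index=False, name=None)
                )
                for cat in matrix.categories
            }
            for tree_path in config.trees:
                tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
                tip_map = {t.label: t.label for t in tree.taxon_namespace}
                dm = patristic_phylum_matrix(tree, tip_map)
                pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(
                    out / f"patristic_{Path(tree_path).stem}.tsv", sep="\t"
                )
                for cat, slopes in slopes_by_cat.items():
                    for mode in ("abs_diff", "quotient"):
                        for method in ("pearson", "spearman"):
                            try:
                                vm = exponent_divergence(slopes, mode=mode)
                                stat, n_pairs = distance_divergence_association(
                                    dm, vm, method=method
                                )
                            except (InsufficientDataError, CogScaleError):
                                stat, n_pairs = np.nan, 0
                            assoc_rows.append(
                                {
                                    "tree": Path(tree_path).stem, "category": cat,
                                    "mode": mode, "method": method,
                                    "statistic": stat, "n_pairs": n_pairs,
                                    "note": "pairs share phyla; not independent",
                                }
                            )
            pd.DataFrame(assoc_rows).to_csv(
                out / "phylo_association.tsv", sep="\t", index=False
            )
            manifest["stages"]["phylo"] = {"n_trees": len(config.trees)}
    except Exception as err:
        manifest["stages"][stage] = {"error": str(err)}
        manifest["status"] = f"failed at stage {stage}"
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise CogScaleError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["status"] = "complete"
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
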