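"""Synthetic count matrices and trees with known scaling ground truth.

Each category's count is generated from a power law of the organism's total
annotation count: mean log10 count = log10_norm + exponent * log10(total),
with Gaussian noise on the log10 scale (log-normal scatter on counts) and
rounding to a non-negative integer.  Optional single breakpoints make the
exponent change at a known position, with the two segments continuous there.
Optional phyla carry per-category exponent offsets, and ``simulate_tree``
can couple those offsets to patristic distance on a random ultrametric tree.

After rounding, the realized row sum replaces the drawn total as the
matrix's ``total`` (the matrix invariant holds exactly); the drawn
generative total is returned in the truth record.

Because the x axis of every downstream fit is the realized total, a spec
whose listed categories sum to much less than the drawn total should name a
``filler_category`` (conventionally "S", the poorly-characterized catch-all
class): it receives ``max(round(T) - sum(other counts), 0)`` so the
realized total tracks the generative target and the listed categories'
exponents are identifiable from the matrix alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from cogscale.annotations import CategoryCountMatrix
from cogscale.errors import ValidationError


@dataclass(frozen=True)
class ScalingLaw:
    """A single power law y = c * x^beta with log-normal scatter.

    ``exponent`` is beta; ``log10_norm`` is log10 c; ``noise_sd`` is the
    standard deviation of additive Gaussian noise on log10 y.
    """

    exponent: float
    log10_norm: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def mean_log10(self, log10_x: np.ndarray) -> np.ndarray:
        return self.log10_norm + self.exponent * np.asarray(log10_x, dtype=float)

    def shifted(self, dexp: float) -> "ScalingLaw":
        return ScalingLaw(self.exponent + dexp, self.log10_norm, self.noise_sd)


@dataclass(frozen=True)
class BreakpointLaw:
    """Two power-law regimes continuous at ``break_x`` (total-annotation units).

    Below the breakpoint the law is ``law_small``; above it the slope is
    ``slope_large`` and the intercept is derived from continuity.
    """

    law_small: ScalingLaw
    slope_large: float
    break_x: float

    def __post_init__(self) -> None:
        if self.break_x <= 0:
            raise ValidationError("break_x must be > 0")

    @property
    def noise_sd(self) -> float:
        return self.law_small.noise_sd

    def mean_log10(self, log10_x: np.ndarray) -> np.ndarray:
        lx = np.asarray(log10_x, dtype=float)
        bx = np.log10(self.break_x)
        below = self.law_small.mean_log10(lx)
        at_break = self.law_small.mean_log10(np.array(bx))
        above = at_break + self.slope_large * (lx - bx)
        return np.where(lx <= bx, below, above)

    def shifted(self, dexp: float) -> "BreakpointLaw":
        return BreakpointLaw(
            self.law_small.shifted(dexp), self.slope_large + dexp, self.break_x
        )


@dataclass(frozen=True)
class PhylumSpec:
    name: str
    fraction: float
    #: additive shift applied to the exponent(s) of each listed category
    exponent_offsets: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationSpec:
    n_organisms: int
    total_range: tuple[float, float]
    laws: dict  # category letter -> ScalingLaw | BreakpointLaw
    phyla: tuple[PhylumSpec, ...] | None = None
    domain_name: str = "Bacteria"
    #: category receiving max(round(T) - other counts, 0); None disables
    filler_category: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.total_range
        if lo < 1 or hi < lo:
            raise ValidationError("total_range must satisfy 1 <= min <= max")
        if self.n_organisms < 1:
            raise ValidationError("n_organisms must be >= 1")
        if not self.laws:
            raise ValidationError("at least one category law required")
        if self.filler_category is not None and self.filler_category in self.laws:
            raise ValidationError("filler_category must not carry its own law")
        if self.phyla is not None:
            frac = sum(p.fraction for p in self.phyla)
            if abs(frac - 1.0) > 1e-9:
                raise ValidationError(f"phylum fractions must sum to 1, got {frac}")


def _effective_law(law, phylum: PhylumSpec | None, category: str):
    if phylum is None:
        return law
    off = phylum.exponent_offsets.get(category, 0.0)
    return law.shifted(off) if off else law


def simulate_matrix(spec: SimulationSpec):
    """Draw a count matrix from the spec's laws.

    Per organism: total T ~ log-uniform over ``total_range``; per category,
    log10 count ~ Normal(law.mean_log10(log10 T), noise_sd), exponentiated
    and rounded to the nearest non-negative integer.  Organisms whose every
    category rounds to zero are dropped (they carry no fit information).

    Returns ``(matrix, truth)`` where truth maps each phylum (or the domain
    when no phyla are given) to its effective per-category law, and carries
    the drawn generative totals under ``"target_total"``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_organisms
    lo, hi = spec.total_range
    log_t = rng.uniform(np.log10(lo), np.log10(hi), size=n)

    if spec.phyla is not None:
        names = [p.name for p in spec.phyla]
        probs = [p.fraction for p in spec.phyla]
        assignment = rng.choice(len(names), size=n, p=probs)
        phylum_of = [spec.phyla[i] for i in assignment]
    else:
        phylum_of = [None] * n

    cats = sorted(spec.laws)
    counts = np.zeros((n, len(cats)), dtype=int)
    for j, cat in enumerate(cats):
        base = spec.laws[cat]
        mean = np.empty(n)
        for i in range(n):
            mean[i] = _effective_law(base, phylum_of[i], cat).mean_log10(log_t[i])
        noisy = mean + rng.normal(0.0, base.noise_sd, size=n)
        counts[:, j] = np.maximum(np.rint(10.0**noisy), 0.0).astype(int)

    orgs = [f"org{i:05d}" for i in range(n)]
    counts_df = pd.DataFrame(counts, index=orgs, columns=cats)
    if spec.filler_category is not None:
        target = np.rint(10.0**log_t).astype(int)
        counts_df[spec.filler_category] = np.maximum(
            target - counts_df.sum(axis=1).to_numpy(), 0
        )
        counts_df = counts_df[sorted(counts_df.columns)]
    taxon = pd.DataFrame(
        {
            "domain": spec.domain_name,
            "phylum": [p.name if p else "unassigned" for p in phylum_of],
        },
        index=orgs,
    )
    nonzero = counts_df.sum(axis=1) > 0
    matrix = CategoryCountMatrix(
        counts=counts_df.loc[nonzero].copy(), taxon=taxon.loc[nonzero].copy()
    )

    truth_groups = spec.phyla if spec.phyla is not None else [None]
    truth = {
        "target_total": pd.Series(10.0**log_t, index=orgs)[nonzero].to_dict(),
        "laws": {
            (p.name if p else spec.domain_name): {
                cat: _effective_law(spec.laws[cat], p, cat) for cat in cats
            }
            for p in truth_groups
        },
    }
    return matrix, truth


def _random_ultrametric_newick(names: list[str], rng: np.random.Generator) -> str:
    """Coalescent-style random ultrametric tree over the given tip names."""
    nodes = [(name, 0.0) for name in rng.permutation(names)]
    height = 0.0
    while len(nodes) > 1:
        height += rng.exponential(1.0 / len(nodes))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (si, hi_), (sj, hj) = nodes[i], nodes[j]
        merged = f"({si}:{height - hi_:.8f},{sj}:{height - hj:.8f})"
        del nodes[j], nodes[i]
        nodes.append((merged, height))
    return nodes[0][0] + ";"


def _mds_first_axis(d: np.ndarray) -> np.ndarray:
    """First principal coordinate of a distance matrix (classical MDS)."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    k = int(np.argmax(vals))
    return vecs[:, k] * np.sqrt(max(vals[k], 0.0))


def simulate_tree(
    phyla: list[str],
    coupling: float,
    seed: int,
    offset_sd: float = 0.2,
):
    """Random ultrametric phylum tree plus exponent offsets tied to it.

    At ``coupling=1`` the offsets are a deterministic 1-D embedding (first
    principal coordinate) of the tree's patristic distances, so phyla far
    apart on the tree tend to get very different offsets; at ``coupling=0``
    the offsets are independent standard-normal draws.  Intermediate values
    mix the two.  Offsets are scaled to standard deviation ``offset_sd``.

    Returns ``(newick, offsets)`` with offsets a phylum -> float dict.
    """
    if len(phyla) < 3:
        raise ValidationError("simulate_tree needs >= 3 phyla")
    if len(set(phyla)) != len(phyla):
        raise ValidationError("phylum names must be unique")
    if not 0.0 <= coupling <= 1.0:
        raise ValidationError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    newick = _random_ultrametric_newick(list(phyla), rng)

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    d = np.array(
        [[pdm.patristic_distance(taxa[a], taxa[b]) for b in phyla] for a in phyla]
    )

    embed = _mds_first_axis(d)
    embed_sd = embed.std()
    coupled = embed / embed_sd if embed_sd > 0 else np.zeros(len(phyla))
    independent = rng.standard_normal(len(phyla))
    raw = coupling * coupled + (1.0 - coupling) * independent
    sd = raw.std()
    offsets = offset_sd * (raw / sd if sd > 0 else raw)
    return newick, dict(zip(phyla, offsets.tolist()))


def write_truth_json(truth: dict, path) -> None:
    """Serialize a simulation truth record (laws flattened to plain dicts)."""
    import json

    def enc(obj):
        if isinstance(obj, ScalingLaw):
            return {
                "kind": "single",
                "exponent": obj.exponent,
                "log10_norm": obj.log10_norm,
                "noise_sd": obj.noise_sd,
            }
        if isinstance(obj, BreakpointLaw):
            return {
                "kind": "breakpoint",
                "exponent_small": obj.law_small.exponent,
                "log10_norm": obj.law_small.log10_norm,
                "noise_sd": obj.noise_sd,
                "slope_large": obj.slope_large,
                "break_x": obj.break_x,
            }
        raise TypeError(type(obj))

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, default=enc, indent=1)
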