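"""Category-shuffle permutation null.

The null permutes the multiset of split category letters across the whole
data set and re-deals them to the same (organism, protein) slots, keeping
each record's letter count.  Per-organism totals and global per-category
totals are therefore conserved exactly, while per-organism category
abundances change — destroying any category-specific scaling relation.
Refitting each category's exponent on shuffled data shows what slopes arise
from totals alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cogscale.annotations import AnnotationRecord, build_count_matrix, split_categories
from cogscale.errors import InsufficientDataError, ValidationError
from cogscale.powerlaw import make_fit_input, ols_fit


@dataclass(frozen=True)
class NullResult:
    category: str
    observed_slope: float
    null_slopes: np.ndarray  # one per permutation; NaN where unfittable
    n_perm: int
    seed: int

    @property
    def n_na(self) -> int:
        return int(np.isnan(self.null_slopes).sum())

    def summary(self) -> dict:
        """Null mean/sd and the empirical two-sided quantile of the observed slope."""
        defined = self.null_slopes[~np.isnan(self.null_slopes)]
        if defined.size == 0:
            return {
                "category": self.category,
                "observed_slope": self.observed_slope,
                "null_mean": float("nan"),
                "null_sd": float("nan"),
                "two_sided_quantile": float("nan"),
                "n_perm": self.n_perm,
                "n_na": self.n_na,
            }
        centered = np.abs(defined - defined.mean())
        obs_c = abs(self.observed_slope - defined.mean())
        return {
            "category": self.category,
            "observed_slope": self.observed_slope,
            "null_mean": float(defined.mean()),
            "null_sd": float(defined.std(ddof=1)) if defined.size > 1 else 0.0,
            "two_sided_quantile": float((centered >= obs_c).mean()),
            "n_perm": self.n_perm,
            "n_na": self.n_na,
        }


def shuffle_categories(
    records: list[AnnotationRecord],
    seed: int,
    *,
    level: str = "letter",
) -> list[AnnotationRecord]:
    """Permute category labels across all annotations.

    ``level='letter'`` (default) permutes the global multiset of split
    letters and re-deals them with the original per-record letter counts;
    ``level='record'`` permutes whole category strings between records.
    Both conserve per-organism totals; letter-level also conserves global
    per-letter totals exactly.
    """
    if not records:
        raise ValidationError("cannot shuffle an empty record list")
    rng = np.random.default_rng(seed)
    if level == "record":
        strings = [r.categories for r in records]
        perm = rng.permutation(len(strings))
        return [
            AnnotationRecord(r.organism_id, r.protein_id, strings[k])
            for r, k in zip(records, perm)
        ]
    if level != "letter":
        raise ValidationError(f"unknown shuffle level {level!r}")
    letters = np.array(
        [c for r in records for c in split_categories(r.categories)], dtype="<U1"
    )
    letters = letters[rng.permutation(len(letters))]
    out = []
    pos = 0
    for r in records:
        k = len(r.categories)
        out.append(
            AnnotationRecord(r.organism_id, r.protein_id, "".join(letters[pos : pos + k]))
        )
        pos += k
    return out


def null_distribution(
    records: list[AnnotationRecord],
    category: str,
    n_perm: int,
    seed: int,
    *,
    taxon_map: pd.DataFrame | None = None,
    zero_policy: str = "drop",
    level: str = "letter",
) -> NullResult:
    """Null slope distribution for one category over ``n_perm`` shuffles.

    Each permutation uses a child seed derived deterministically from the
    master seed; permutations where the category has too few nonzero
    organisms are recorded as NaN, never dropped.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if taxon_map is None:
        orgs = sorted({r.organism_id for r in records})
        taxon_map = pd.DataFrame(
            {"domain": "unknown", "phylum": "unknown"}, index=pd.Index(orgs)
        )

    def _slope(recs):
        matrix = build_count_matrix(recs, taxon_map, permissive=True)
        try:
            return ols_fit(make_fit_input(matrix, category, zero_policy=zero_policy)).slope
        except InsufficientDataError:
            return float("nan")
        except Exception:  # degenerate design after shuffling
            return float("nan")

    observed = _slope(records)
    child_seeds = np.random.SeedSequence(seed).spawn(n_perm)
    null_slopes = np.empty(n_perm)
    for i, ss in enumerate(child_seeds):
        child = int(ss.generate_state(1)[0] % (2**31))
        null_slopes[i] = _slope(shuffle_categories(records, child, level=level))
    return NullResult(
        category=category,
        observed_slope=observed,
        null_slopes=null_slopes,
        n_perm=n_perm,
        seed=seed,
    )


def null_summary_table(results: list[NullResult]) -> pd.DataFrame:
    return pd.DataFrame([r.summary() for r in results])
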