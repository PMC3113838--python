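"""Conservation scoring, two-group tests and gene-set overlap statistics.

Conservation of a human miRNA across metazoans is summarized on a 3-level
scale from its cross-species presence list (pre-compiled, e.g. by BLAST):
0 = human-specific; 1 = conserved within primates (or, conservatively, in
up to two taxonomic orders); 2 = conserved in more than two orders.

Group comparisons of structural/thermodynamic features between mitomiRs and
control miRNAs use a two-tailed Welch t-test (unequal variances) and a
two-sided Fisher-Snedecor F-test of variances; significance at p < 0.05.
Gene-set enrichment of an overlap uses the upper-tail hypergeometric
probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "conservation_score",
    "score_conservation_table",
    "load_bundled_conservation",
    "welch_t_test",
    "f_variance_test",
    "overlap_percentage",
    "hypergeom_enrichment",
    "compare_groups",
    "bh_adjust",
]

HUMAN = "Hsa"


def conservation_score(orders_present: set[str], species: list[str]) -> int:
    """Score cross-species conservation of a human miRNA.

    0 if the species list is human only; 2 if more than two distinct
    taxonomic orders are represented; otherwise 1 (conserved in primates, or
    in exactly two orders — the conservative reading of the boundary case).
    The list must include human (the rule presumes a human miRNA).
    """
    species_set = set(species)
    if not species_set:
        raise ValueError("species list is empty")
    if HUMAN not in species_set:
        raise ValueError(f"species list must include human ({HUMAN!r})")
    if species_set == {HUMAN}:
        return 0
    if len(set(orders_present)) > 2:
        return 2
    return 1


def score_conservation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`conservation_score` per miRNA to a long-format table
    with columns ``mirna_id``, ``species``, ``order``."""
    rows = []
    for mid, grp in table.groupby("mirna_id", sort=False):
        score = conservation_score(set(grp["order"]), list(grp["species"]))
        rows.append(
            {
                "mirna_id": mid,
                "n_species": grp["species"].nunique(),
                "n_orders": grp["order"].nunique(),
                "score": score,
            }
        )
    return pd.DataFrame(rows)


def load_bundled_conservation() -> pd.DataFrame:
    """The published cross-species presence lists of the 13 mitochondrially
    enriched human miRNAs (long format: mirna_id, species, order)."""
    ref = resources.files("mitomir").joinpath("data/mitomir_conservation.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-tailed Student's t-test assuming unequal variances (Welch), with
    Welch-Satterthwaite degrees of freedom.  Returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def f_variance_test(a, b) -> tuple[float, float]:
    """Two-sided Fisher-Snedecor F-test of equal variances.

    F = larger sample variance / smaller, with the matching degrees of
    freedom; p is twice the upper tail, capped at 1 (symmetric convention,
    so swapping the samples leaves the result unchanged)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    if va >= vb:
        num_v, den_v, dfn, dfd = va, vb, len(a) - 1, len(b) - 1
    else:
        num_v, den_v, dfn, dfd = vb, va, len(b) - 1, len(a) - 1
    if den_v == 0:
        return float("inf"), 0.0
    F = num_v / den_v
    p = min(1.0, 2.0 * float(stats.f.sf(F, dfn, dfd)))
    return float(F), p


def overlap_percentage(target_set, reference_set) -> float:
    """100 x |target ∩ reference| / |target|."""
    target = set(target_set)
    if not target:
        raise ValueError("target set is empty")
    return 100.0 * len(target & set(reference_set)) / len(target)


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of drawing ``k``
    category members in a list of ``n`` from a universe of ``N`` containing
    ``K`` category members."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    t_pvalue: float
    F: float
    f_pvalue: float
    significant_t: bool
    significant_f: bool


def compare_groups(
    table: pd.DataFrame,
    features: list[str],
    group_col: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-group comparison (Welch t and two-sided F), one row
    per feature.  ``table`` must contain exactly two groups in ``group_col``."""
    groups = list(pd.unique(table[group_col]))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    rows = []
    for feat in features:
        a = ga[feat].dropna().to_numpy()
        b = gb[feat].dropna().to_numpy()
        t, pt = welch_t_test(a, b)
        F, pf = f_variance_test(a, b)
        rows.append(
            GroupComparison(
                feature=feat,
                mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)),
                mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)),
                t=t, t_pvalue=pt, F=F, f_pvalue=pf,
                significant_t=pt < alpha, significant_f=pf < alpha,
            ).__dict__
        )
    out = pd.DataFrame(rows)
    out.attrs["groups"] = {"a": groups[0], "b": groups[1]}
    return out
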