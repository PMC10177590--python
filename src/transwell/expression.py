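"""qPCR relative expression (dCt / ddCt) and the accompanying test toolkit.

Expression of each target gene is normalized to a housekeeping gene
(default GAPDH) as ``dCt = Ct(gene) - Ct(housekeeping)`` per replicate;
between-group comparisons use ``ddCt = mean dCt(a) - mean dCt(b)`` and fold
change ``2^(-ddCt)``. Replicate-matched housekeeping pairing is used when
the replicate counts line up, otherwise the group-mean housekeeping Ct is
subtracted (the convention that reproduces published group-mean arithmetic).

The statistics here are implemented from their closed forms (pooled/Welch
two-sample t, one-way ANOVA sums of squares, Sidak step adjustment) with
scipy supplying only the reference distributions, so the test suite can
cross-check them against scipy's high-level routines as an independent
route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .model import ValidationError

DEFAULT_HOUSEKEEPING = "GAPDH"


@dataclass
class CtTable:
    """Long-format cycle-threshold table: (group, gene, replicate, ct)."""

    data: pd.DataFrame
    housekeeping_gene: str = DEFAULT_HOUSEKEEPING

    def __post_init__(self) -> None:
        required = {"group", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"Ct table missing column(s): {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValidationError("all Ct values must be > 0")
        for group, grp in self.data.groupby("group"):
            if self.housekeeping_gene not in set(grp["gene"]):
                raise ValidationError(
                    f"housekeeping gene {self.housekeeping_gene!r} missing in "
                    f"group {group!r}")

    @classmethod
    def read_csv(cls, path: str, housekeeping_gene: str = DEFAULT_HOUSEKEEPING
                 ) -> "CtTable":
        return cls(pd.read_csv(path), housekeeping_gene=housekeeping_gene)


def delta_ct(table: CtTable) -> pd.DataFrame:
    """Per-replicate dCt of every gene against the housekeeping gene.

    Within each group: replicate-matched subtraction when the gene and the
    housekeeping gene have the same replicate count, otherwise subtraction
    of the group-mean housekeeping Ct. Returns columns
    ``group, gene, replicate, ct, dct, pairing``.
    """
    out_rows = []
    for group, grp in table.data.groupby("group", sort=True):
        hk = grp[grp["gene"] == table.housekeeping_gene].sort_values("replicate")
        hk_ct = hk["ct"].to_numpy()
        hk_mean = float(hk_ct.mean())
        for gene, gg in grp.groupby("gene", sort=True):
            gg = gg.sort_values("replicate")
            cts = gg["ct"].to_numpy()
            if gene == table.housekeeping_gene and len(cts) == len(hk_ct):
                ref, pairing = hk_ct, "replicate"
            elif len(cts) == len(hk_ct):
                ref, pairing = hk_ct, "replicate"
            else:
                ref, pairing = hk_mean, "group_mean"
            dct = cts - ref
            for rep, ct, d in zip(gg["replicate"], cts, np.atleast_1d(dct)):
                out_rows.append({"group": group, "gene": gene, "replicate": rep,
                                 "ct": ct, "dct": float(d), "pairing": pairing})
    return pd.DataFrame(out_rows)


def delta_delta_ct(dct_a: Sequence[float], dct_b: Sequence[float]
                   ) -> Tuple[float, float]:
    """``ddCt = mean dCt(a) - mean dCt(b)``; fold change ``2^(-ddCt)``."""
    a = np.asarray(dct_a, dtype=float)
    b = np.asarray(dct_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    ddct = float(a.mean() - b.mean())
    return ddct, 2.0 ** (-ddct)


def two_group_test(values_a: Sequence[float], values_b: Sequence[float],
                   variant: str = "student_pooled") -> Tuple[float, float]:
    """Two-tailed two-sample t-test; pooled-variance Student's by default.

    ``variant`` is ``"student_pooled"`` or ``"welch"``. Two identical
    zero-variance groups are the degenerate no-evidence case: t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if ma == mb:
            return 0.0, 1.0
        return math.copysign(math.inf, ma - mb), 0.0
    if variant == "student_pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    elif variant == "welch":
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        raise ValidationError(f"unknown t-test variant {variant!r}")
    t = (ma - mb) / se
    p = 2.0 * _stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classical one-way ANOVA from the between/within sums of squares.

    With two groups the F statistic equals the squared pooled t statistic.
    All-identical constant groups carry no evidence: F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValidationError("every group needs >= 2 values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(_stats.f.sf(f, df_between, df_within))
    return float(f), p


def sidak_adjust(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: ``1 - (1 - p)^m``, clipped to 1.

    ``m`` defaults to the number of p-values supplied; it is exposed because
    the relevant family of comparisons is a modeling choice.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = int(m) if m is not None else len(p)
    if m < 1:
        raise ValidationError("m must be >= 1")
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


@dataclass
class ExpressionResult:
    """Relative expression of one gene in one group vs a reference group."""

    gene: str
    group: str
    dct_mean: float
    dct_sd: Optional[float]
    reference_group: Optional[str] = None
    ddct: Optional[float] = None
    fold_change: Optional[float] = None
    p_value: Optional[float] = None
    adjusted_p_value: Optional[float] = None


def compare_groups(table: CtTable, group_a: str, group_b: str,
                   genes: Optional[Sequence[str]] = None,
                   m: Optional[int] = None,
                   variant: str = "student_pooled") -> pd.DataFrame:
    """dCt / ddCt / fold change / t-test p (raw and Sidak) for each gene.

    ``group_b`` is the reference; positive ddCt means *lower* expression in
    ``group_a``. ``m`` is the size of the comparison family for the Sidak
    adjustment (defaults to the number of genes compared).
    """
    dct = delta_ct(table)
    genes = list(genes) if genes is not None else sorted(
        g for g in dct["gene"].unique() if g != table.housekeeping_gene)
    rows = []
    raw_ps = []
    for gene in genes:
        a = dct[(dct["group"] == group_a) & (dct["gene"] == gene)]["dct"].to_numpy()
        b = dct[(dct["group"] == group_b) & (dct["gene"] == gene)]["dct"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValidationError(f"gene {gene!r} missing in one of the groups")
        ddct, fold = delta_delta_ct(a, b)
        if len(a) >= 2 and len(b) >= 2:
            _, p = two_group_test(a, b, variant=variant)
        else:
            p = float("nan")
        raw_ps.append(p)
        rows.append({"gene": gene, "group": group_a, "reference_group": group_b,
                     "dct_mean": float(a.mean()),
                     "dct_sd": float(a.std(ddof=1)) if len(a) >= 2 else float("nan"),
                     "ref_dct_mean": float(b.mean()),
                     "ddct": ddct, "fold_change": fold, "p_value": p})
    adj = sidak_adjust(np.nan_to_num(np.array(raw_ps), nan=1.0),
                       m if m is not None else len(genes))
    out = pd.DataFrame(rows)
    out["adjusted_p_value"] = np.where(np.isnan(raw_ps), float("nan"), adj)
    return out
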