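"""Single-cell qPCR workflow: QC, dCt expression, and reactivity calls.

Cells are screened on two control genes (default Gapdh and Oaz1); a cell
is discarded when *both* controls are undetected (Ct above the cutoff,
default 32).  Expression is ``2^(-dCt)`` with ``dCt = Ct_gene -
Ct_reference`` per cell.  The whole-population comparison is a two-sample
t-test on expression with Bonferroni correction over the gene panel.  For
the heterogeneity analysis, dCt values are z-normalized per gene against
the mean and standard deviation pooled over both groups (sign flipped so
that higher expression gives positive z), and a gene is called up- or
down-regulated when the Student-t 95% confidence interval of the treated
cells' mean z excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CtTable",
    "GeneCall",
    "qc_filter",
    "delta_ct",
    "population_comparison",
    "normalize_pooled_z",
    "ci_call",
    "gene_calls",
    "calls_to_frame",
]


@dataclass
class CtTable:
    """Cells x genes Ct matrix with group labels and control designation."""

    ct: pd.DataFrame  # index: cell_id, columns: genes
    group: pd.Series  # index: cell_id
    control_genes: tuple[str, str] = ("Gapdh", "Oaz1")
    reference_gene: str = "Gapdh"
    ceiling: float = 40.0

    def __post_init__(self) -> None:
        if self.reference_gene not in self.control_genes:
            raise ValueError("reference_gene must be one of the control genes")
        missing = [g for g in self.control_genes if g not in self.ct.columns]
        if missing:
            raise ValueError(f"control genes missing from table: {missing}")
        if not self.ct.index.equals(self.group.index):
            raise ValueError("ct and group must share the same cell index")
        vals = self.ct.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite <= 0).any():
            raise ValueError("Ct values must be positive")
        if finite.size and (finite > self.ceiling + 1e-9).any():
            raise ValueError("Ct values must not exceed the censoring ceiling")

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.ct.columns if g not in self.control_genes]

    def censored(self) -> pd.DataFrame:
        """Ct matrix with undetected (NaN) measurements set to the ceiling."""
        return self.ct.fillna(self.ceiling)

    def to_csv(self, path) -> None:
        out = self.ct.copy()
        out.insert(0, "group", self.group)
        # undetected measurements are written as blanks
        out.to_csv(path, na_rep="")

    @classmethod
    def from_csv(
        cls,
        path,
        control_genes: tuple[str, str] = ("Gapdh", "Oaz1"),
        reference_gene: str = "Gapdh",
        ceiling: float = 40.0,
    ) -> "CtTable":
        df = pd.read_csv(path, index_col="cell_id")
        group = df.pop("group")
        return cls(
            ct=df.astype(float),
            group=group,
            control_genes=control_genes,
            reference_gene=reference_gene,
            ceiling=ceiling,
        )


@dataclass
class GeneCall:
    """Per-gene population fold change and heterogeneity-based call."""

    gene: str
    fold_change: float
    p_raw: float
    p_bonf: float
    z_mean_treated: float
    ci95: tuple[float, float]
    call: str  # up | down | ns | non_informative

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if self.call == "up" and not lo > 0:
            raise ValueError("call=up requires CI lower bound > 0")
        if self.call == "down" and not hi < 0:
            raise ValueError("call=down requires CI upper bound < 0")


# ---------------------------------------------------------------------------


def qc_filter(table: CtTable, cutoff: float = 32.0, mode: str = "both") -> CtTable:
    """Remove cells without detectable control-gene expression.

    Default ``mode='both'``: a cell is removed iff *both* control genes
    have Ct above the cutoff.  ``mode='either'`` removes a cell when
    either control fails.
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    ct = table.censored()
    fails = pd.DataFrame(
        {g: ct[g] > cutoff for g in table.control_genes}
    )
    drop = fails.all(axis=1) if mode == "both" else fails.any(axis=1)
    keep = ~drop
    return replace(table, ct=table.ct.loc[keep], group=table.group.loc[keep])


def delta_ct(table: CtTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell dCt (Ct_gene - Ct_reference) and expression 2^(-dCt).

    Undetected target measurements enter at the censoring ceiling, so
    their expression is near-zero but finite.  Cells whose reference gene
    is itself undetected get missing (NaN) values.
    """
    ct = table.censored()
    ref = ct[table.reference_gene].copy()
    ref_undetected = ref >= table.ceiling - 1e-9
    ref[ref_undetected] = np.nan
    genes = [g for g in table.genes if g != table.reference_gene]
    dct = ct[genes].sub(ref, axis=0)
    expression = np.exp2(-dct)
    return dct, expression


def population_comparison(
    expression: pd.DataFrame,
    groups: pd.Series,
    control_label: str,
    treated_label: str,
    n_genes_for_correction: int | None = None,
) -> pd.DataFrame:
    """Whole-population fold change and Bonferroni-corrected t-test per gene.

    Fold change is the ratio of group mean expressions
    (treated / control).  Returns a DataFrame indexed by gene with columns
    ``fold_change, p_raw, p_bonf``.
    """
    n_genes = n_genes_for_correction or expression.shape[1]
    rows = {}
    for gene in expression.columns:
        a = expression.loc[groups == treated_label, gene].dropna().to_numpy()
        b = expression.loc[groups == control_label, gene].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows[gene] = (np.nan, np.nan, np.nan)
            continue
        mb = b.mean()
        fold = a.mean() / mb if mb > 0 else np.nan
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(sps.ttest_ind(a, b).pvalue)
        rows[gene] = (fold, p, min(1.0, p * n_genes))
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["fold_change", "p_raw", "p_bonf"]
    )
    out.index.name = "gene"
    return out


def normalize_pooled_z(dct: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pooled z-normalization of dCt per gene over all cells.

    ``z_i = (mean_pooled - dCt_i) / sd_pooled`` (sample sd), so lower dCt
    (higher expression) maps to positive z.  Genes with zero pooled sd are
    non-informative and returned as all-missing columns.
    """
    mean = dct.mean(axis=0, skipna=True)
    sd = dct.std(axis=0, ddof=1, skipna=True)
    counts = dct.notna().sum(axis=0)
    if (counts < 2).any():
        bad = list(dct.columns[counts < 2])
        raise ValueError(f"need >= 2 pooled cells per gene; too few for {bad}")
    z = dct.rsub(mean, axis=1).div(sd, axis=1)
    non_informative = list(dct.columns[(sd == 0) | sd.isna()])
    z[non_informative] = np.nan
    return z, non_informative


def ci_call(
    z: pd.DataFrame,
    groups: pd.Series,
    treated_label: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """95% t-interval of the treated cells' mean z, and up/down/ns call.

    Returns a DataFrame indexed by gene with columns
    ``z_mean_treated, ci_lo, ci_hi, call``.
    """
    zt = z.loc[groups == treated_label]
    rows = {}
    for gene in z.columns:
        vals = zt[gene].dropna().to_numpy()
        n = len(vals)
        if n < 2:
            rows[gene] = (np.nan, np.nan, np.nan, "non_informative")
            continue
        m = vals.mean()
        half = sps.t.ppf(1 - alpha / 2, n - 1) * vals.std(ddof=1) / math.sqrt(n)
        lo, hi = m - half, m + half
        if lo > 0:
            call = "up"
        elif hi < 0:
            call = "down"
        else:
            call = "ns"
        rows[gene] = (m, lo, hi, call)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["z_mean_treated", "ci_lo", "ci_hi", "call"]
    )
    out.index.name = "gene"
    return out


def gene_calls(
    table: CtTable,
    control_label: str,
    treated_label: str,
    qc_cutoff: float = 32.0,
    qc_mode: str = "both",
    n_genes_for_correction: int | None = None,
    alpha: float = 0.05,
    target_genes: Sequence[str] | None = None,
) -> tuple[list[GeneCall], pd.DataFrame]:
    """Full workflow: QC -> dCt -> population t-tests -> pooled z -> CI calls.

    Returns the per-gene calls for the target panel plus the z matrix
    (cells x genes) for heatmap export.
    """
    filtered = qc_filter(table, cutoff=qc_cutoff, mode=qc_mode)
    if filtered.ct.shape[0] == 0:
        raise ValueError("QC removed all cells")
    dct, expression = delta_ct(filtered)
    panel = list(target_genes) if target_genes is not None else [
        g for g in filtered.target_genes if g != filtered.reference_gene
    ]
    n_corr = n_genes_for_correction or len(panel)
    pop = population_comparison(
        expression[panel], filtered.group, control_label, treated_label, n_corr
    )
    z, non_informative = normalize_pooled_z(dct[panel])
    ci = ci_call(z, filtered.group, treated_label, alpha=alpha)

    calls = []
    for gene in panel:
        call = "non_informative" if gene in non_informative else ci.loc[gene, "call"]
        calls.append(
            GeneCall(
                gene=gene,
                fold_change=float(pop.loc[gene, "fold_change"]),
                p_raw=float(pop.loc[gene, "p_raw"]),
                p_bonf=float(pop.loc[gene, "p_bonf"]),
                z_mean_treated=float(ci.loc[gene, "z_mean_treated"]),
                ci95=(float(ci.loc[gene, "ci_lo"]), float(ci.loc[gene, "ci_hi"])),
                call=call,
            )
        )
    return calls, z


def calls_to_frame(calls: Sequence[GeneCall]) -> pd.DataFrame:
    rows = [
        {
            "gene": c.gene,
            "fold_change": c.fold_change,
            "p_raw": c.p_raw,
            "p_bonf": c.p_bonf,
            "z_mean_treated": c.z_mean_treated,
            "ci_lo": c.ci95[0],
            "ci_hi": c.ci95[1],
            "call": c.call,
        }
        for c in calls
    ]
    return pd.DataFrame(rows).set_index("gene")
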