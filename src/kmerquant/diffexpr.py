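"""Differential expression: geometric-mean fold changes, Welch t-tests,
Benjamini-Hochberg FDR and significance calling.

The model compares two groups of replicates on the normalized log2
expression matrix.  Per gene:

* the fold change is the ratio of the groups' geometric means on the
  linear (pseudocounted, depth-normalized) scale, i.e.
  ``2 ** (mean(log2 trt) - mean(log2 ref))``;
* the test is the two-sample t-test with unequal variances (Welch),
  with Welch-Satterthwaite degrees of freedom, applied to the log2
  values (variance-stabilized scale; the test is invariant to the
  per-sample additive offsets' mean);
* p-values are adjusted by the Benjamini-Hochberg step-up procedure
  over the testable genes;
* a gene is called ``up`` iff fold_change > fc_threshold (default 1.61)
  AND fdr < alpha (default 0.05), both strict; ``down`` is the mirror
  call with fold_change < 1/fc_threshold.

Genes that are absent, or that have zero variance in both groups with
unequal means (no within-group information at all), are ``untestable``:
they are excluded from the BH family size m and labeled, never silently
dropped.  Zero variance in both groups with *equal* means yields t = 0,
p = 1 (a well-defined non-discovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ContractError, ValidationError
from .quantify import ExpressionMatrix

DEFAULT_FC_THRESHOLD = 1.61
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DEConfig:
    """Significance-calling thresholds."""

    fc_threshold: float = DEFAULT_FC_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValidationError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample-to-group assignment plus the (reference, treatment) contrast."""

    groups: dict[str, str]  # sample_id -> group label
    contrast: tuple[str, str]  # (reference, treatment)

    def __post_init__(self) -> None:
        ref, trt = self.contrast
        for label in (ref, trt):
            n = sum(1 for g in self.groups.values() if g == label)
            if n < 2:
                raise ValidationError(
                    f"contrast group {label!r} has {n} samples; need >= 2 "
                    "(3 replicates per condition recommended)"
                )

    def samples_of(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    @classmethod
    def from_series(cls, groups: pd.Series,
                    contrast: tuple[str, str]) -> "ExperimentDesign":
        return cls(groups=dict(groups.items()), contrast=contrast)


def geometric_fold_change(reference, treatment) -> tuple[float, float]:
    """Fold change as the ratio of geometric means (treatment / reference).

    Values must be strictly positive (the normalization pseudocount
    guarantees this upstream); the geometric mean is computed as
    ``2 ** mean(log2 values)``.

    Returns ``(fold_change, log2fc)``.
    """
    ref = np.asarray(reference, float)
    trt = np.asarray(treatment, float)
    if ref.size == 0 or trt.size == 0:
        raise ContractError("fold change of an empty group")
    if np.any(ref <= 0) or np.any(trt <= 0):
        raise ContractError(
            "geometric fold change requires strictly positive values "
            "(apply the normalization pseudocount first)"
        )
    log2fc = float(np.mean(np.log2(trt)) - np.mean(np.log2(ref)))
    return 2.0 ** log2fc, log2fc


def welch_t_test(group_a, group_b, two_sided: bool = True
                 ) -> tuple[float, float, float]:
    """Two-sample t-test with unequal variances (Welch).

    Returns ``(t, df, p)`` where df is the Welch-Satterthwaite
    approximation.  Degenerate inputs: both groups constant with equal
    means give ``(0, nan, 1)``; both constant with unequal means give
    ``(nan, nan, nan)`` (untestable — no variance information).  The
    one-sided alternative is ``mean(a) > mean(b)``.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float("nan"), 1.0
        return float("nan"), float("nan"), float("nan")
    alternative = "two-sided" if two_sided else "greater"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries (untestable genes) are excluded from the family size m
    and returned as NaN.
    """
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    testable = ~np.isnan(p)
    if np.any((p[testable] < 0) | (p[testable] > 1)):
        raise ContractError("p-values must lie in [0, 1]")
    if testable.any():
        out[testable] = stats.false_discovery_control(p[testable], method="bh")
    return out


def call_significant(table: pd.DataFrame, config: DEConfig) -> pd.DataFrame:
    """Fill the ``call`` column from fold_change and fdr (strict thresholds)."""
    fc, fdr = table["fold_change"], table["fdr"]
    call = pd.Series("not_significant", index=table.index, dtype=object)
    call[(fc > config.fc_threshold) & (fdr < config.alpha)] = "up"
    call[(fc < 1.0 / config.fc_threshold) & (fdr < config.alpha)] = "down"
    call[fdr.isna() | fc.isna()] = "untestable"
    out = table.copy()
    out["call"] = call
    return out


class DifferentialExpression:
    """Welch-t / BH differential-expression model on normalized expression.

    Parameters
    ----------
    matrix:
        Normalized log2 expression (:class:`ExpressionMatrix` with
        scale ``normalized-log2``).
    design:
        Sample grouping and the (reference, treatment) contrast; both
        contrast groups need >= 2 replicates.
    """

    def __init__(self, matrix: ExpressionMatrix, design: ExperimentDesign):
        if matrix.scale != "normalized-log2":
            raise ValidationError(
                "differential expression is computed on the normalized matrix"
            )
        self.matrix = matrix
        self.design = design
        missing = [
            s
            for label in design.contrast
            for s in design.samples_of(label)
            if s not in matrix.samples
        ]
        if missing:
            raise ValidationError(f"design samples missing from matrix: {missing}")

    def fit(self, config: DEConfig | None = None) -> "DEResults":
        """Test every gene; returns a :class:`DEResults`."""
        config = config or DEConfig()
        ref_label, trt_label = self.design.contrast
        ref = self.matrix.data[self.design.samples_of(ref_label)].to_numpy(float)
        trt = self.matrix.data[self.design.samples_of(trt_label)].to_numpy(float)

        n_genes = ref.shape[0]
        cols = {
            name: np.full(n_genes, np.nan)
            for name in ("mean_ref", "mean_trt", "fold_change", "log2fc",
                         "t", "df", "p")
        }
        for i in range(n_genes):
            r, t = ref[i], trt[i]
            if np.isnan(r).any() or np.isnan(t).any():
                continue  # absent gene -> untestable
            # log2-scale means; geometric means on the linear scale
            mr, mt = r.mean(), t.mean()
            cols["mean_ref"][i] = 2.0 ** mr
            cols["mean_trt"][i] = 2.0 ** mt
            cols["log2fc"][i] = mt - mr
            cols["fold_change"][i] = 2.0 ** (mt - mr)
            t_stat, df, p = welch_t_test(t, r, two_sided=config.two_sided)
            cols["t"][i], cols["df"][i], cols["p"][i] = t_stat, df, p

        table = pd.DataFrame(cols, index=self.matrix.data.index)
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table = call_significant(table, config)
        return DEResults(table=table, config=config, design=self.design)


@dataclass
class DEResults:
    """Per-gene differential-expression table plus summary/plot helpers."""

    table: pd.DataFrame
    config: DEConfig
    design: ExperimentDesign
    _order: tuple[str, ...] = field(
        default=("mean_ref", "mean_trt", "fold_change", "log2fc",
                 "t", "df", "p", "fdr", "call"),
        repr=False,
    )

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["call"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["call"] == "down"]

    def summary(self) -> str:
        calls = self.table["call"].value_counts()
        ref, trt = self.design.contrast
        lines = [
            f"Differential expression: {trt} vs {ref} "
            f"(fold > {self.config.fc_threshold}, FDR < {self.config.alpha})",
            f"  genes tested:    {int(self.table['p'].notna().sum())}"
            f" / {len(self.table)}",
            f"  upregulated:     {int(calls.get('up', 0))}",
            f"  downregulated:   {int(calls.get('down', 0))}",
            f"  not significant: {int(calls.get('not_significant', 0))}",
            f"  untestable:      {int(calls.get('untestable', 0))}",
        ]
        top = self.table.loc[self.up].sort_values("fdr").head(10)
        if len(top):
            lines.append("  top upregulated genes:")
            for gene, row in top.iterrows():
                lines.append(
                    f"    {gene:16s} fold={row.fold_change:7.2f} "
                    f"p={row.p:.3g} FDR={row.fdr:.3g}"
                )
        return "\n".join(lines)

    def to_tsv(self, path, meta: dict | None = None) -> None:
        from .io import write_matrix_tsv

        write_matrix_tsv(self.table[list(self._order)], path, meta=meta)

    def plot_volcano(self, ax=None):
        """log2 fold change vs -log10 FDR, significant calls highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table.dropna(subset=["fdr"])
        colors = t["call"].map(
            {"up": "crimson", "down": "steelblue"}
        ).fillna("0.6")
        ax.scatter(t["log2fc"], -np.log10(t["fdr"].clip(lower=1e-300)),
                   s=8, c=colors, alpha=0.7, linewidths=0)
        ax.axvline(np.log2(self.config.fc_threshold), ls=":", c="k", lw=0.8)
        ax.axvline(-np.log2(self.config.fc_threshold), ls=":", c="k", lw=0.8)
        ax.axhline(-np.log10(self.config.alpha), ls=":", c="k", lw=0.8)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 FDR")
        return ax
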