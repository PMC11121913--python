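"""Two-group differential expression for small-RNA count data.

The procedure mirrors the classic exact-test workflow for count matrices
with few replicates: counts-per-million (CPM) normalisation, removal of
features consistently expressed below a raw-count-derived CPM threshold,
a common negative-binomial dispersion estimated by conditional maximum
likelihood, and a conditional exact test per feature, followed by
Benjamini-Hochberg FDR control.  Significance requires FDR < alpha and
|log2FC| > a minimum effect size (both strict).

The NB parameterisation is ``variance = mu + phi * mu**2``; ``phi = 0``
degenerates to Poisson.  The exact test conditions on the total count of
the two groups: under a common mean, the group-A sum given the total
follows the ratio of NB-sum (or Poisson-sum) split probabilities, and the
p-value sums the probabilities of all splits at most as likely as the one
observed.

``DifferentialExpressionModel`` wraps the pipeline statsmodels-style:
construct from a count matrix plus group labels, call :meth:`fit`, get a
``DifferentialExpressionResults`` with the per-feature table, the
dispersion estimate and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleSheet

__all__ = [
    "cpm_normalize",
    "filter_low_expression",
    "estimate_common_dispersion",
    "exact_test",
    "bh_adjust",
    "call_de",
    "equalize_library_sizes",
    "DispersionEstimate",
    "DifferentialExpressionModel",
    "DifferentialExpressionResults",
]


# ---------------------------------------------------------------------------
# Normalisation and filtering
# ---------------------------------------------------------------------------

def cpm_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: ``counts / library_size * 1e6`` per sample."""
    lib = np.asarray(matrix.library_sizes, dtype=float)
    if np.any(lib <= 0):
        j = int(np.argmax(lib <= 0))
        raise ValueError(f"zero library size for sample {matrix.sample_ids[j]!r}")
    cpm = matrix.counts / lib[None, :] * 1e6
    return pd.DataFrame(cpm, index=matrix.feature_ids, columns=matrix.sample_ids)


def filter_low_expression(
    matrix: CountMatrix, min_raw: int = 5, min_fraction: float = 0.5
) -> list[str]:
    """Features expressed above a raw-count-derived CPM floor.

    The threshold is the CPM equivalent of ``min_raw`` counts in the
    smallest library; a feature is kept iff its CPM reaches it in at
    least ``ceil(min_fraction * n_samples)`` samples.
    """
    if matrix.n_features == 0:
        raise ValueError("empty count matrix")
    threshold = min_raw / float(np.min(matrix.library_sizes)) * 1e6
    cpm = cpm_normalize(matrix).to_numpy()
    required = int(np.ceil(min_fraction * matrix.n_samples))
    passing = (cpm >= threshold).sum(axis=1) >= required
    return [f for f, ok in zip(matrix.feature_ids, passing) if ok]


def equalize_library_sizes(counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """Scale counts to the geometric-mean library size, round-half-even.

    The conditional exact test assumes exchangeable library sizes; this
    deterministic pseudo-count adjustment is the smallest way to get
    there for near-equal libraries.
    """
    lib = np.asarray(library_sizes, dtype=float)
    target = float(np.exp(np.mean(np.log(lib))))
    scaled = counts * (target / lib)[None, :]
    return np.asarray(np.round(scaled), dtype=np.int64)  # numpy rounds half to even


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionEstimate:
    """Common NB dispersion phi (variance = mu + phi mu^2); 0 = Poisson."""

    phi: float

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be non-negative")


def _cond_loglik(counts_by_group: list[np.ndarray], phi: float) -> float:
    """Conditional log-likelihood of within-group counts given group sums.

    ``counts_by_group``: one (features x replicates) integer array per
    group, library sizes already equalised.  Terms constant in phi are
    dropped.  The phi -> 0 limit is the multinomial (Poisson) value
    ``-sum_g z_g log n_g``.
    """
    total = 0.0
    for y in counts_by_group:
        n = y.shape[1]
        z = y.sum(axis=1)
        if phi <= 1e-12:
            total += float(np.sum(-z * np.log(n)))
            continue
        r = 1.0 / phi
        total += float(
            np.sum(
                gammaln(y + r).sum(axis=1)
                - n * gammaln(r)
                + gammaln(n * r)
                - gammaln(z + n * r)
            )
        )
    return total


def estimate_common_dispersion(
    matrix: CountMatrix,
    groups: list[str] | np.ndarray,
    phi_max: float = 10.0,
    tol: float = 1e-4,
) -> DispersionEstimate:
    """Common dispersion by conditional ML, golden-section over [0, phi_max].

    Counts are first equalised to the geometric-mean library size so the
    conditional argument holds.  Returns phi = 0 when the Poisson limit
    fits at least as well as any interior point.
    """
    groups = np.asarray(groups)
    eq = equalize_library_sizes(matrix.counts, matrix.library_sizes)
    by_group: list[np.ndarray] = []
    for g in pd.unique(groups):
        cols = np.flatnonzero(groups == g)
        if cols.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        by_group.append(eq[:, cols])

    invphi = (np.sqrt(5) - 1) / 2
    a, b = 0.0, phi_max
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = _cond_loglik(by_group, c), _cond_loglik(by_group, d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _cond_loglik(by_group, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _cond_loglik(by_group, d)
    phi_hat = (a + b) / 2
    if _cond_loglik(by_group, 0.0) >= _cond_loglik(by_group, phi_hat):
        return DispersionEstimate(0.0)
    return DispersionEstimate(float(phi_hat))


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _split_log_weights(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log conditional probabilities of every split (x, total - x)."""
    x = np.arange(total + 1)
    if phi <= 0:
        # Poisson sums -> binomial(total, n_a / (n_a + n_b))
        p = n_a / (n_a + n_b)
        logw = (
            gammaln(total + 1)
            - gammaln(x + 1)
            - gammaln(total - x + 1)
            + x * np.log(p)
            + (total - x) * np.log1p(-p)
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logw = (
            gammaln(x + r_a) - gammaln(x + 1)
            + gammaln(total - x + r_b) - gammaln(total - x + 1)
        )
        logw -= logsumexp(logw)
    return logw


def exact_test(
    group_a: np.ndarray | list[int],
    group_b: np.ndarray | list[int],
    phi: float,
) -> float:
    """Conditional exact p-value for equality of means of two count groups.

    Operates on library-size-equalised replicate counts.  Conditional on
    the total, the p-value sums the probabilities of all splits whose
    probability does not exceed that of the observed split (with a small
    relative tolerance so exact ties count as ties in floating point).
    """
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    s_a, total = int(a.sum()), int(a.sum() + b.sum())
    if total == 0:
        return 1.0
    logw = _split_log_weights(total, a.size, b.size, phi)
    log_obs = logw[s_a]
    in_tail = logw <= log_obs + 1e-10
    p = float(np.exp(logsumexp(logw[in_tail]) - logsumexp(logw)))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Multiple testing and significance calls
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    records: pd.DataFrame, alpha: float = 0.05, min_abs_log2fc: float = 0.6
) -> pd.DataFrame:
    """Set direction and the significance flag (strict thresholds)."""
    out = records.copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out["significant"] = (out["fdr"] < alpha) & (out["log2fc"].abs() > min_abs_log2fc)
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DifferentialExpressionModel:
    """Exact-test differential expression of treated vs control counts.

    Parameters
    ----------
    matrix
        Raw counts, features x samples.
    groups
        Per-sample labels, ``"control"`` / ``"treated"`` (any two labels
        work; the second in ``contrast`` is the numerator of log2FC).
    contrast
        ``(reference, treatment)`` pair; default ``("control", "treated")``.
    min_raw, min_fraction
        Low-expression filter parameters (see :func:`filter_low_expression`).
    prior_count
        Pseudo-CPM added to both group means before the log2 ratio.
    """

    def __init__(
        self,
        matrix: CountMatrix,
        groups,
        contrast: tuple[str, str] = ("control", "treated"),
        min_raw: int = 5,
        min_fraction: float = 0.5,
        prior_count: float = 0.5,
    ) -> None:
        self.matrix = matrix
        self.groups = np.asarray(list(groups))
        if self.groups.size != matrix.n_samples:
            raise ValueError("one group label required per sample")
        self.contrast = contrast
        for label in contrast:
            if int((self.groups == label).sum()) < 2:
                raise ValueError(f"group {label!r} needs at least 2 samples")
        self.min_raw = min_raw
        self.min_fraction = min_fraction
        self.prior_count = prior_count

    @classmethod
    def from_sample_sheet(
        cls,
        matrix: CountMatrix,
        sheet: SampleSheet,
        regimen: str,
        which: str = "mirna",
        **kwargs,
    ) -> "DifferentialExpressionModel":
        """Build the model for one regimen using the sheet's library pairing."""
        sub = sheet.subset(regimen=regimen)
        sub.require_replicates(2)
        libs = sub.mirna_libraries() if which == "mirna" else sub.mrna_libraries()
        sel = matrix.subset_samples(libs)
        return cls(sel, sub.conditions(), **kwargs)

    def fit(
        self, alpha: float = 0.05, min_abs_log2fc: float = 0.6
    ) -> "DifferentialExpressionResults":
        kept = filter_low_expression(self.matrix, self.min_raw, self.min_fraction)
        filtered = self.matrix.subset_features(kept)
        dispersion = estimate_common_dispersion(filtered, self.groups)

        eq = equalize_library_sizes(filtered.counts, filtered.library_sizes)
        ref, trt = self.contrast
        cols_ref = np.flatnonzero(self.groups == ref)
        cols_trt = np.flatnonzero(self.groups == trt)
        p_values = np.array(
            [
                exact_test(eq[i, cols_ref], eq[i, cols_trt], dispersion.phi)
                for i in range(filtered.n_features)
            ]
        )

        cpm = cpm_normalize(filtered).to_numpy()
        mean_ref = cpm[:, cols_ref].mean(axis=1)
        mean_trt = cpm[:, cols_trt].mean(axis=1)
        c = self.prior_count
        log2fc = np.log2((mean_trt + c) / (mean_ref + c))

        table = pd.DataFrame(
            {
                "feature_id": filtered.feature_ids,
                "log2fc": log2fc,
                "mean_cpm": cpm.mean(axis=1),
                "p_value": p_values,
                "fdr": bh_adjust(p_values),
            }
        )
        table = call_de(table, alpha=alpha, min_abs_log2fc=min_abs_log2fc)
        return DifferentialExpressionResults(
            self, table, dispersion, alpha, min_abs_log2fc, n_input_features=self.matrix.n_features
        )


class DifferentialExpressionResults:
    """Fitted DE results: per-feature table, dispersion, thresholds."""

    def __init__(
        self,
        model: DifferentialExpressionModel,
        table: pd.DataFrame,
        dispersion: DispersionEstimate,
        alpha: float,
        min_abs_log2fc: float,
        n_input_features: int,
    ) -> None:
        self.model = model
        self.table = table
        self.dispersion = dispersion
        self.alpha = alpha
        self.min_abs_log2fc = min_abs_log2fc
        self.n_input_features = n_input_features

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def significant_ids(self, direction: str | None = None) -> set[str]:
        sig = self.significant
        if direction is not None:
            sig = sig[sig["direction"] == direction]
        return set(sig["feature_id"])

    def summary(self) -> str:
        sig = self.significant
        n_up = int((sig["direction"] == "up").sum())
        n_down = int((sig["direction"] == "down").sum())
        lines = [
            "Differential expression (conditional exact test)",
            "=" * 48,
            f"features tested        {len(self.table):>8d}"
            f"   (of {self.n_input_features} before filtering)",
            f"common dispersion phi  {self.dispersion.phi:>8.4f}",
            f"FDR threshold          {self.alpha:>8.3g}   |log2FC| > {self.min_abs_log2fc:g}",
            f"significant            {len(sig):>8d}   ({n_up} up, {n_down} down)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
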