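"""Per-gene CpG observed/expected ratios and mixture-model classification.

Gene-body DNA methylation leaves a mutational footprint: methylated
cytosines in CpG context deaminate to T at an elevated rate, so the coding
sequences of historically methylated genes are depleted of CpG
dinucleotides.  The CpG_o/e statistic,

    CpG_o/e = f_CpG / (f_C * f_G),

compares the observed CpG frequency of a CDS with the frequency expected
from its C and G content; values well below 1 indicate depletion.  Across
insects with active DNA methylation the per-gene distribution is bimodal,
and a two-component Gaussian mixture separates the putatively methylated
(low) mode from the unmethylated (high) mode.  The decision boundary is the
intersection point of the two scaled component densities.

The mixture model is exposed as :class:`CpGMixtureClassifier`, a
scikit-learn style estimator (``fit`` / ``predict`` on a 1-d array of
CpG_o/e values); ``fit_mixture`` / ``intersection_threshold`` / ``classify``
are thin functional wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "CpGProfile",
    "MixtureFit",
    "MethylationCall",
    "CpGMixtureClassifier",
    "compute_cpg_oe",
    "filter_range",
    "fit_mixture",
    "intersection_threshold",
    "classify",
]

LOW, HIGH = "low", "high"

#: variance floor: EM components may not collapse below this variance
VAR_FLOOR = 1e-4


@dataclass(frozen=True)
class CpGProfile:
    """Dinucleotide bookkeeping behind one gene's CpG_o/e value.

    ``l_counted`` is the number of unambiguous (A/C/G/T) positions;
    ``cpg_oe`` is None when undefined (no C, no G, or fewer than two
    counted positions).
    """

    gene_id: str
    n_cg: int
    n_c: int
    n_g: int
    l_counted: int
    cpg_oe: float | None


@dataclass(frozen=True)
class MethylationCall:
    gene_id: str
    cpg_oe: float
    category: str  # LOW or HIGH


@dataclass(frozen=True)
class MixtureFit:
    """Two-component univariate normal mixture with the density-intersection
    threshold used for classification.  Component 0 is the low-mean
    (putatively methylated) component by construction."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool
    threshold: float


def compute_cpg_oe(nt_seq: str, gene_id: str = "") -> CpGProfile:
    """CpG_o/e of a coding sequence.

    Counts are taken over unambiguous positions only; a non-ACGT position
    also breaks a potential CG pair spanning it.  Frequencies use the
    dinucleotide denominator (l_counted - 1) for CpG and the mononucleotide
    denominator l_counted for C and G.
    """
    if len(nt_seq) < 2:
        raise ValueError("sequence shorter than 2 nt")
    seq = nt_seq.upper()
    acgt = set("ACGT")
    n_c = n_g = n_cg = l_counted = 0
    prev_ok_c = False  # previous position is an unambiguous C
    for ch in seq:
        ok = ch in acgt
        if ok:
            l_counted += 1
            if ch == "C":
                n_c += 1
            elif ch == "G":
                n_g += 1
                if prev_ok_c:
                    n_cg += 1
        prev_ok_c = ok and ch == "C"
    if n_c == 0 or n_g == 0 or l_counted < 2:
        return CpGProfile(gene_id, n_cg, n_c, n_g, l_counted, None)
    f_cpg = n_cg / (l_counted - 1)
    f_c = n_c / l_counted
    f_g = n_g / l_counted
    return CpGProfile(gene_id, n_cg, n_c, n_g, l_counted, f_cpg / (f_c * f_g))


def filter_range(
    profiles: Iterable[CpGProfile], lo: float = 0.0, hi: float = 2.0
) -> tuple[list[CpGProfile], dict[str, int]]:
    """Keep profiles with cpg_oe strictly inside (lo, hi).

    Undefined values are dropped.  Returns (retained, drop-counts) where
    the counts record how many genes each rule removed.
    """
    if lo >= hi:
        raise ValueError(f"invalid range: lo={lo} >= hi={hi}")
    kept: list[CpGProfile] = []
    dropped = {"undefined": 0, "out_of_range": 0}
    for p in profiles:
        if p.cpg_oe is None:
            dropped["undefined"] += 1
        elif lo < p.cpg_oe < hi:
            kept.append(p)
        else:
            dropped["out_of_range"] += 1
    return kept, dropped


class CpGMixtureClassifier(BaseEstimator):
    """Two-component Gaussian mixture classifier for CpG_o/e values.

    Fits a univariate mixture ``w0*N(m0,s0^2) + w1*N(m1,s1^2)`` by EM with a
    deterministic median-split initialisation, relabels so the low-mean
    component comes first, and places the decision threshold at the
    intersection of the two scaled component densities between the means.
    ``predict`` returns 0 (low / putatively methylated) for values below the
    threshold and 1 (high) otherwise.

    Parameters
    ----------
    tol : float
        EM stops when the log-likelihood improvement drops below this.
    max_iter : int
        Iteration cap; exceeding it sets ``converged_ = False``.
    min_values : int
        Minimum number of finite input values required by ``fit``.

    Attributes (after fit)
    ----------
    weights_, means_, sds_ : ndarray of shape (2,)
    threshold_ : float
    loglik_ : float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 500, min_values: int = 50):
        self.tol = tol
        self.max_iter = max_iter
        self.min_values = min_values

    # -- EM ----------------------------------------------------------------
    def fit(self, X, y=None) -> "CpGMixtureClassifier":
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < self.min_values:
            raise ValueError(
                f"need at least {self.min_values} finite values, got {x.size}"
            )
        if np.ptp(x) == 0:
            raise ValueError("zero variance input")

        w, mu, sd = self._init_params(x)
        loglik = -np.inf
        n_iter = 0
        converged = False
        loglik_path: list[float] = []
        for n_iter in range(1, self.max_iter + 1):
            # E step: responsibilities of component 0
            log_p = np.stack(
                [np.log(w[k]) + norm.logpdf(x, mu[k], sd[k]) for k in (0, 1)]
            )
            log_tot = np.logaddexp(log_p[0], log_p[1])
            new_loglik = float(log_tot.sum())
            loglik_path.append(new_loglik)
            resp = np.exp(log_p - log_tot)  # (2, n)
            # M step
            nk = resp.sum(axis=1)
            w = nk / x.size
            mu = (resp @ x) / nk
            var = np.array(
                [
                    float(resp[k] @ (x - mu[k]) ** 2) / nk[k]
                    for k in (0, 1)
                ]
            )
            sd = np.sqrt(np.maximum(var, VAR_FLOOR))
            if new_loglik - loglik < self.tol and np.isfinite(loglik):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik

        order = np.argsort(mu)
        self.weights_ = w[order]
        self.means_ = mu[order]
        self.sds_ = sd[order]
        self.loglik_ = loglik
        self.loglik_path_ = loglik_path
        self.n_iter_ = n_iter
        self.converged_ = converged
        if not converged:
            import warnings

            warnings.warn(
                f"EM did not converge in {self.max_iter} iterations", RuntimeWarning
            )
        self.threshold_ = self._intersection_threshold()
        return self

    @staticmethod
    def _init_params(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # deterministic: split at the median, moments of the two halves
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        if hi.size == 0:  # all values equal the median on the right
            lo, hi = x[x < med], x[x >= med]
        w = np.array([lo.size, hi.size], dtype=float) / x.size
        mu = np.array([lo.mean(), hi.mean()])
        sd = np.sqrt(
            np.maximum(np.array([lo.var(), hi.var()]), VAR_FLOOR)
        )
        return w, mu, sd

    # -- threshold ---------------------------------------------------------
    def _intersection_threshold(self) -> float:
        (w0, w1) = self.weights_
        (m0, m1) = self.means_
        (s0, s1) = self.sds_
        if not m0 < m1:
            raise ValueError("degenerate fit: component means coincide")
        root = _density_intersection(w0, m0, s0, w1, m1, s1)
        if root is not None:
            return root
        # no density-crossing between the means: fall back to the point of
        # equal posterior responsibility, located by bisection
        return _bisect_posterior(w0, m0, s0, w1, m1, s1)

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return (x >= self.threshold_).astype(int)

    def mixture_fit_(self) -> MixtureFit:
        """Snapshot of the fitted parameters as an immutable record."""
        return MixtureFit(
            weights=(float(self.weights_[0]), float(self.weights_[1])),
            means=(float(self.means_[0]), float(self.means_[1])),
            sds=(float(self.sds_[0]), float(self.sds_[1])),
            loglik=self.loglik_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            threshold=self.threshold_,
        )


def _density_intersection(
    w0: float, m0: float, s0: float, w1: float, m1: float, s1: float
) -> float | None:
    """Root of w0*phi(x;m0,s0) = w1*phi(x;m1,s1) strictly between the means.

    Equal variances give a linear equation; unequal variances a quadratic.
    Returns None when no root falls in (m0, m1).
    """
    c = math.log(w0 / s0) - math.log(w1 / s1)
    if math.isclose(s0, s1, rel_tol=0, abs_tol=1e-12):
        s2 = s0 * s0
        # linear: (m1-m0)/s2 * x + (m0^2-m1^2)/(2 s2) + c = 0
        x = (s2 * c + (m1 * m1 - m0 * m0) / 2.0) / (m1 - m0)
        return x if m0 < x < m1 else None
    a = 1.0 / (2 * s1 * s1) - 1.0 / (2 * s0 * s0)
    b = m0 / (s0 * s0) - m1 / (s1 * s1)
    c0 = m1 * m1 / (2 * s1 * s1) - m0 * m0 / (2 * s0 * s0) + c
    disc = b * b - 4 * a * c0
    if disc < 0:
        return None
    roots = [(-b + sign * math.sqrt(disc)) / (2 * a) for sign in (+1.0, -1.0)]
    inside = [r for r in roots if m0 < r < m1]
    if not inside:
        return None
    return min(inside)  # at most one crossing lies between the means


def _bisect_posterior(
    w0: float, m0: float, s0: float, w1: float, m1: float, s1: float
) -> float:
    def g(x: float) -> float:
        return (math.log(w0) + norm.logpdf(x, m0, s0)) - (
            math.log(w1) + norm.logpdf(x, m1, s1)
        )

    lo, hi = m0, m1
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:  # same sign: return midpoint of the interval
        return 0.5 * (m0 + m1)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if gm == 0 or hi - lo < 1e-14:
            return mid
        if glo * gm < 0:
            hi, ghi = mid, gm
        else:
            lo, glo = mid, gm
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_mixture(
    values: Sequence[float], tol: float = 1e-8, max_iter: int = 500
) -> MixtureFit:
    """Fit the two-component mixture and return its parameter record."""
    est = CpGMixtureClassifier(tol=tol, max_iter=max_iter).fit(values)
    return est.mixture_fit_()


def intersection_threshold(fit: MixtureFit) -> float:
    """Density-intersection threshold of an already-fitted mixture."""
    (w0, w1), (m0, m1), (s0, s1) = fit.weights, fit.means, fit.sds
    if not m0 < m1:
        raise ValueError("degenerate fit: component means coincide")
    root = _density_intersection(w0, m0, s0, w1, m1, s1)
    if root is not None:
        return root
    return _bisect_posterior(w0, m0, s0, w1, m1, s1)


def classify(
    profiles: Iterable[CpGProfile | tuple[str, float]], threshold: float
) -> tuple[list[MethylationCall], dict[str, float]]:
    """Bin genes at the threshold: cpg_oe < threshold -> low, else high.

    Accepts CpGProfile objects or (gene_id, cpg_oe) pairs.  Returns the
    calls and a summary with the low/high fractions.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    calls: list[MethylationCall] = []
    for p in profiles:
        if isinstance(p, CpGProfile):
            gid, value = p.gene_id, p.cpg_oe
        else:
            gid, value = p
        if value is None:
            continue
        category = LOW if value < threshold else HIGH
        calls.append(MethylationCall(gid, float(value), category))
    n = len(calls)
    n_low = sum(1 for c in calls if c.category == LOW)
    summary = {
        "n": n,
        "n_low": n_low,
        "n_high": n - n_low,
        "fraction_low": n_low / n if n else float("nan"),
        "fraction_high": (n - n_low) / n if n else float("nan"),
    }
    return calls, summary


def calls_by_gene(calls: Iterable[MethylationCall]) -> Mapping[str, str]:
    """gene_id -> category lookup used by the orthogroup stage."""
    return {c.gene_id: c.category for c in calls}
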