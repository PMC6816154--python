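"""Method- and reader-agreement statistics for paired measurements.

Implements the four statistics used to compare two measurement methods (or
two readers) on the same subjects:

* Bland-Altman bias and 95% limits of agreement, LOA = bias +/- 1.96 * SD
  of the paired differences;
* coefficient of variance, CV = SD between measurements / mean * 100%,
  with the within-subject SD pooled as the root mean of per-subject
  variances (the difference-SD convention is also reported);
* intraclass correlation coefficient (two-way random effects, absolute
  agreement, single measurement by default; consistency form selectable),
  from the standard subjects x raters mean-squares decomposition;
* Cohen's kappa for categorical ratings (ILT types).

These are deliberately bespoke, direct implementations of the formulas;
independent library routines are used only as cross-checks in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgreementReport",
    "bland_altman",
    "cv_percent",
    "icc",
    "cohen_kappa",
    "agreement_report",
]


@dataclass
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    icc: float
    cv_percent: float
    n: int

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be equal-length 1D sequences")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired inputs must be finite")
    return a, b


def bland_altman(a, b) -> dict:
    """Bias and 95% limits of agreement of paired differences a - b.

    bias = mean(a - b); sd_diff = sample SD (n-1 denominator);
    LOA = bias +/- 1.96 * sd_diff.
    """
    a, b = _paired(a, b)
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd_diff": sd,
    }


def cv_percent(a, b, method: str = "within_subject") -> float:
    """Coefficient of variance (%) between two measurements per subject.

    "within_subject": per-subject SD of the two values, pooled as
    sqrt(mean per-subject variance), divided by the grand mean.
    "difference": SD of the paired differences over the grand mean.
    """
    a, b = _paired(a, b)
    grand = float(np.concatenate([a, b]).mean())
    if grand <= 0:
        raise ValueError("grand mean must be positive")
    if method == "within_subject":
        per_subj_var = (a - b) ** 2 / 2.0  # two-value sample variance (ddof=1)
        sd = float(np.sqrt(per_subj_var.mean()))
    elif method == "difference":
        sd = float((a - b).std(ddof=1))
    else:
        raise ValueError(f"unknown CV method {method!r}")
    return 100.0 * sd / grand


def icc(a, b, form: str = "absolute") -> float:
    """Intraclass correlation coefficient for two raters/methods.

    form "absolute":  two-way random effects, absolute agreement, single
    measurement — ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n).
    form "consistency": ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE).
    Computed from the subjects x raters mean-squares decomposition.
    """
    a, b = _paired(a, b)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.stack([a, b], axis=1)  # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0:
        if np.array_equal(a, b):
            return 1.0
        raise ValueError("degenerate data: zero total variance with unequal columns")
    if form == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float((msr - mse) / denom)


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa: chance-corrected agreement of two categorical ratings.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    Perfect agreement with degenerate marginals (p_e = 1) is defined as 1.
    """
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    if la.shape != lb.shape or la.ndim != 1 or len(la) < 1:
        raise ValueError("label vectors must be equal-length, non-empty 1D sequences")
    cats = np.union1d(la, lb)
    n = len(la)
    p_o = float(np.mean(la == lb))
    p_e = 0.0
    for c in cats:
        p_e += float(np.mean(la == c)) * float(np.mean(lb == c))
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("expected agreement is 1 but observed agreement is not")
    return (p_o - p_e) / (1.0 - p_e)


def agreement_report(a, b, icc_form: str = "absolute") -> AgreementReport:
    """Bundle the continuous-measurement agreement statistics for one metric."""
    a, b = _paired(a, b)
    ba = bland_altman(a, b)
    try:
        cv = cv_percent(a, b)
    except ValueError:
        cv = float("nan")  # CV undefined for near-zero or signed means
    return AgreementReport(
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        sd_diff=ba["sd_diff"],
        icc=icc(a, b, icc_form),
        cv_percent=cv,
        n=len(a),
    )
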