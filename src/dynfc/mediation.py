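"""Bootstrap mediation of behavioral sex differences by brain integration.

The question: is a sex difference in a behavioral measure carried by the
prevalence of the integrated brain state?  Variables are first screened —
a candidate must correlate with *both* sex and the integration measure at
p < alpha/m (Bonferroni, m = 66 by default).  For each candidate the
single-mediator path model is fit by OLS:

    M = i_m + a * sex + e_m           (path a: sex -> mediator)
    Y = i_y + c' * sex + b * M + e_y  (paths c' and b)
    Y = i_t + c * sex + e_t           (total effect)

with sex coded 1 = male / 2 = female (left on that coding) and mediator and
outcome standardized to unit variance on the analysis sample.  The OLS
identity c = c' + a*b holds exactly.  The indirect effect a*b gets a 95%
percentile CI from resampling subjects with replacement (5000 draws by
default); the mediation is called significant when the CI excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bonferroni_screen

DEFAULT_N_BOOT = 5000


@dataclass
class MediationInput:
    """Standardized single-mediator data for one outcome variable."""

    sex: np.ndarray  # 1/2 coding, not standardized
    mediator: np.ndarray  # variance 1
    outcome: np.ndarray  # variance 1

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, float)
        self.mediator = np.asarray(self.mediator, float)
        self.outcome = np.asarray(self.outcome, float)
        n = self.sex.size
        if self.mediator.size != n or self.outcome.size != n:
            raise ValueError("sex, mediator and outcome must align")
        for name, v in (("mediator", self.mediator), ("outcome", self.outcome)):
            if abs(v.var(ddof=0) - 1.0) > 1e-8:
                raise ValueError(f"{name} must be standardized to unit variance")

    @classmethod
    def from_raw(cls, sex, mediator, outcome) -> "MediationInput":
        """Standardize mediator and outcome (population SD) on the sample."""
        m = np.asarray(mediator, float)
        y = np.asarray(outcome, float)
        return cls(
            sex=np.asarray(sex, float),
            mediator=(m - m.mean()) / m.std(ddof=0),
            outcome=(y - y.mean()) / y.std(ddof=0),
        )

    @property
    def n(self) -> int:
        return self.sex.size


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    c_total: float
    indirect_ab: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool


@dataclass
class ScreenResult:
    variable: str
    r_sex: float
    p_sex: float
    r_mediator: float
    p_mediator: float
    candidate: bool


def screen(
    behavior_table: pd.DataFrame,
    sex,
    mediator,
    m: int = 66,
    alpha: float = 0.05,
    variables: list[str] | None = None,
) -> list[ScreenResult]:
    """Bonferroni-corrected correlation screen of behavioral variables.

    A variable is a mediation candidate iff its Pearson correlation with sex
    *and* with the integration measure both reach p < alpha/m.  (For a
    binary group code, the correlation p-value is algebraically the pooled
    two-sample t-test p-value.)  Rows with missing values are dropped per
    variable; constant variables are skipped with a warning.
    """
    import warnings

    sex = np.asarray(sex, float)
    mediator = np.asarray(mediator, float)
    variables = variables or [c for c in behavior_table.columns if c != "subject_id"]
    results = []
    for var in variables:
        vals = pd.to_numeric(behavior_table[var], errors="coerce").to_numpy(float)
        ok = np.isfinite(vals) & np.isfinite(mediator)
        v, s, med = vals[ok], sex[ok], mediator[ok]
        if v.size < 3 or v.std() == 0:
            warnings.warn(f"variable {var}: constant or too few complete cases; skipped")
            continue
        r1, p1 = sps.pearsonr(v, s)
        r2, p2 = sps.pearsonr(v, med)
        passed = bool(bonferroni_screen([p1], m=m, alpha=alpha)[0]
                      and bonferroni_screen([p2], m=m, alpha=alpha)[0])
        results.append(ScreenResult(var, float(r1), float(p1), float(r2), float(p2), passed))
    return results


def _ols_paths(sex: np.ndarray, med: np.ndarray, out: np.ndarray):
    """Closed-form OLS for the three path regressions (with intercepts)."""
    n = sex.size
    sc = sex - sex.mean()
    mc = med - med.mean()
    yc = out - out.mean()
    sxx = sc @ sc
    if sxx <= 0:
        raise ValueError("sex is constant: paths undefined")
    a = (sc @ mc) / sxx
    c_total = (sc @ yc) / sxx
    # Y ~ sex + mediator: solve the centered 2x2 normal equations
    smm = mc @ mc
    sxm = sc @ mc
    det = sxx * smm - sxm**2
    if det <= 0 or smm <= 0:
        raise ValueError("sex and mediator are collinear: paths undefined")
    sxy = sc @ yc
    smy = mc @ yc
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    return float(a), float(b), float(c_prime), float(c_total)


def fit_paths(data: MediationInput):
    """Point estimates (a, b, c', c_total); c_total = c' + a*b exactly."""
    return _ols_paths(data.sex, data.mediator, data.outcome)


def bootstrap_indirect(
    data: MediationInput,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MediationResult:
    """Percentile bootstrap CI for the indirect effect a*b.

    Subjects are resampled with replacement; the paths are refit per
    resample (variables are *not* re-standardized inside resamples).
    Degenerate resamples with constant sex are redrawn; the attempt budget
    is 100 * n_boot.
    """
    if data.n < 30:
        raise ValueError("bootstrap mediation needs n >= 30")
    a, b, c_prime, c_total = fit_paths(data)
    rng = np.random.default_rng(seed)
    sex, med, out = data.sex, data.mediator, data.outcome
    n = data.n
    ab = np.empty(n_boot)
    filled = 0
    attempts = 0
    max_attempts = 100 * n_boot
    batch = n_boot
    while filled < n_boot:
        if attempts >= max_attempts:
            raise RuntimeError("too many degenerate bootstrap resamples (constant sex)")
        take = min(batch, n_boot - filled)
        idx = rng.integers(0, n, size=(take, n))
        s = sex[idx]
        m = med[idx]
        y = out[idx]
        attempts += take
        good = s.std(axis=1) > 0
        s, m, y = s[good], m[good], y[good]
        k = s.shape[0]
        if k == 0:
            continue
        sc = s - s.mean(axis=1, keepdims=True)
        mc = m - m.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", sc, sc)
        smm = np.einsum("ij,ij->i", mc, mc)
        sxm = np.einsum("ij,ij->i", sc, mc)
        sxy = np.einsum("ij,ij->i", sc, yc)
        smy = np.einsum("ij,ij->i", mc, yc)
        det = sxx * smm - sxm**2
        ok = (det > 0) & (smm > 0)
        k_ok = int(ok.sum())
        if k_ok == 0:
            continue
        a_b = (sxm[ok] / sxx[ok])
        b_b = (sxx[ok] * smy[ok] - sxm[ok] * sxy[ok]) / det[ok]
        ab[filled : filled + k_ok] = a_b * b_b
        filled += k_ok
    lo, hi = np.percentile(ab, [2.5, 97.5])
    return MediationResult(
        a=a, b=b, c_prime=c_prime, c_total=c_total,
        indirect_ab=a * b, ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, significant=bool(lo > 0 or hi < 0),
    )


def mediate_candidates(
    behavior_table: pd.DataFrame,
    sex,
    mediator,
    m: int = 66,
    alpha: float = 0.05,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen, then bootstrap-mediate every candidate variable.

    Returns one row per screened variable with the screening correlations
    and, for candidates, the path estimates and bootstrap CI.
    """
    sex = np.asarray(sex, float)
    mediator = np.asarray(mediator, float)
    screened = screen(behavior_table, sex, mediator, m=m, alpha=alpha)
    rows = []
    for sr in screened:
        row = {
            "variable": sr.variable,
            "r_sex": sr.r_sex, "p_sex": sr.p_sex,
            "r_mediator": sr.r_mediator, "p_mediator": sr.p_mediator,
            "candidate": sr.candidate,
        }
        if sr.candidate:
            vals = pd.to_numeric(behavior_table[sr.variable], errors="coerce").to_numpy(float)
            ok = np.isfinite(vals) & np.isfinite(mediator)
            data = MediationInput.from_raw(sex[ok], mediator[ok], vals[ok])
            res = bootstrap_indirect(data, n_boot=n_boot, seed=seed)
            row.update(
                a=res.a, b=res.b, c_prime=res.c_prime, c_total=res.c_total,
                indirect_ab=res.indirect_ab, ci_low=res.ci_low, ci_high=res.ci_high,
                significant=res.significant,
            )
        rows.append(row)
    return pd.DataFrame(rows)
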