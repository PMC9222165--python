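"""Method-agreement statistics for paired angle and type measurements.

Quantifies how closely automated measurements track a reference reading the
way method-comparison studies report it: mean +/- SD of the paired
differences, mean absolute error, the intraclass correlation coefficient
(two-way random effects, absolute agreement, single measures — ICC(2,1) —
with an F-based 95% CI after McGraw & Wong 1996), Bland-Altman limits of
agreement (mean difference +/- 1.96 SD, sample SD with n-1 denominator), and
for the binary Graf type the raw agreement rate and Cohen's kappa.

The ICC and kappa computations are implemented here from the mean-squares /
contingency definitions; the test suite cross-checks them against independent
implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass(frozen=True)
class PairedAngles:
    """Equal-length paired angle readings (method vs reference), degrees."""

    method_values: tuple[float, ...]
    reference_values: tuple[float, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.method_values, dtype=float)
        r = np.asarray(self.reference_values, dtype=float)
        if m.shape != r.shape or m.ndim != 1 or m.size < 2:
            raise ValueError("need two equal-length series of length >= 2")
        if not (np.isfinite(m).all() and np.isfinite(r).all()):
            raise ValueError("angle values must be finite")
        object.__setattr__(self, "method_values", tuple(float(x) for x in m))
        object.__setattr__(self, "reference_values", tuple(float(x) for x in r))

    @classmethod
    def from_arrays(cls, method, reference) -> "PairedAngles":
        return cls(tuple(np.asarray(method, float)), tuple(np.asarray(reference, float)))

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.method_values, self.reference_values])


@dataclass(frozen=True)
class AgreementReport:
    mean_diff: float
    sd_diff: float
    mae: float
    icc: float
    icc_ci: tuple[float, float]
    ba_limits: tuple[float, float]
    pct_within_limits: float
    n: int

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "mae": self.mae,
            "icc": self.icc,
            "icc_ci_low": self.icc_ci[0],
            "icc_ci_high": self.icc_ci[1],
            "ba_lower": self.ba_limits[0],
            "ba_upper": self.ba_limits[1],
            "pct_within_limits": self.pct_within_limits,
        }


@dataclass(frozen=True)
class ClassificationReport:
    agreement_rate: float  # percent
    kappa: float
    confusion: tuple[tuple[int, int], tuple[int, int]]  # rows: a in (I, II)

    def as_dict(self) -> dict:
        return {
            "agreement_rate": self.agreement_rate,
            "kappa": self.kappa,
            "confusion": [list(r) for r in self.confusion],
        }


def icc_2_1(p: PairedAngles, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares; the CI uses the F-based
    interval of McGraw & Wong (1996).  With fewer than 5 subjects the CI is
    reported as (nan, nan).  A dataset with zero total variance is perfect
    agreement by definition: ICC = 1.
    """
    data = p.as_matrix()
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        return 1.0, (1.0, 1.0)
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    if n < 5:
        return float(icc), (float("nan"), float("nan"))
    alpha = 1.0 - confidence
    if mse == 0 and msc == 0:
        return float(icc), (1.0, 1.0)
    fc = msc / mse if mse > 0 else np.inf
    num = (k - 1) * (n - 1) * (k * icc * fc + n * (1 + (k - 1) * icc) - k * icc) ** 2
    den = (n - 1) * k**2 * icc**2 * fc**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = num / den
    f2u = sstats.f.ppf(1 - alpha / 2, n - 1, v)
    f2l = sstats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f2u * mse) / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
    return float(icc), (float(lower), float(upper))


def angle_agreement(p: PairedAngles) -> AgreementReport:
    """Bland-Altman style agreement summary of method-minus-reference."""
    m = np.asarray(p.method_values)
    r = np.asarray(p.reference_values)
    d = m - r
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    mae = float(np.abs(d).mean())
    lower = mean_diff - 1.96 * sd_diff
    upper = mean_diff + 1.96 * sd_diff
    pct = float(100.0 * np.mean((d >= lower) & (d <= upper)))
    icc, ci = icc_2_1(p)
    return AgreementReport(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        mae=mae,
        icc=icc,
        icc_ci=ci,
        ba_limits=(float(lower), float(upper)),
        pct_within_limits=pct,
        n=d.size,
    )


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), marginal-product expectation.

    Defined as 1 when both raters are constant and identical (p_e = 1).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b) or not a:
        raise ValueError("label lists must be equal-length and non-empty")
    cats = sorted(set(a) | set(b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    conf = np.zeros((len(cats), len(cats)), dtype=float)
    for x, y in zip(a, b):
        conf[idx[x], idx[y]] += 1
    total = conf.sum()
    p_o = np.trace(conf) / total
    p_e = float((conf.sum(axis=1) / total) @ (conf.sum(axis=0) / total))
    if np.isclose(p_e, 1.0):
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def classification_report(labels_a: Sequence, labels_b: Sequence) -> ClassificationReport:
    """Agreement rate, kappa, and the 2x2 confusion table over Graf types."""
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b) or not a:
        raise ValueError("label lists must be equal-length and non-empty")
    order = ["I", "II"]
    idx = {c: i for i, c in enumerate(order)}
    unknown = (set(a) | set(b)) - set(order)
    if unknown:
        raise ValueError(f"labels must be Graf types I/II, got {sorted(unknown, key=str)}")
    conf = np.zeros((2, 2), dtype=int)
    for x, y in zip(a, b):
        conf[idx[x], idx[y]] += 1
    rate = float(100.0 * np.trace(conf) / conf.sum())
    return ClassificationReport(
        agreement_rate=rate,
        kappa=cohen_kappa(a, b),
        confusion=((int(conf[0, 0]), int(conf[0, 1])), (int(conf[1, 0]), int(conf[1, 1]))),
    )


# ---------------------------------------------------------------------------
# CSV I/O and report rendering
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ["id", "alpha", "beta", "graf_type"]


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    """Read an id/alpha/beta/graf_type measurement table."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV {path} lacks columns: {missing}")
    return df[MEASUREMENT_COLUMNS].copy()


def evaluate_tables(pred: pd.DataFrame, ref: pd.DataFrame) -> dict:
    """Per-angle agreement plus type classification for matching ids.

    Raises on id mismatch, listing the orphan ids from each side.
    """
    pred_ids = set(pred["id"])
    ref_ids = set(ref["id"])
    if pred_ids != ref_ids:
        raise ValueError(
            "prediction/reference id mismatch; "
            f"only in predictions: {sorted(pred_ids - ref_ids)}; "
            f"only in references: {sorted(ref_ids - pred_ids)}"
        )
    merged = pred.merge(ref, on="id", suffixes=("_method", "_ref")).sort_values("id")
    out = {
        "alpha": angle_agreement(
            PairedAngles.from_arrays(merged["alpha_method"], merged["alpha_ref"])
        ),
        "beta": angle_agreement(
            PairedAngles.from_arrays(merged["beta_method"], merged["beta_ref"])
        ),
        "classification": classification_report(
            merged["graf_type_method"].tolist(), merged["graf_type_ref"].tolist()
        ),
    }
    return out


def format_report(report: dict) -> str:
    """Human-readable summary in the layout of a method-comparison table."""
    lines = ["angle  n  mean_diff  sd_diff  MAE  ICC (95% CI)  LoA  %within"]
    for angle in ("alpha", "beta"):
        r: AgreementReport = report[angle]
        lines.append(
            f"{angle:5s}  {r.n}  {r.mean_diff:+.2f}  {r.sd_diff:.2f}  {r.mae:.2f}  "
            f"{r.icc:.2f} ({r.icc_ci[0]:.2f}~{r.icc_ci[1]:.2f})  "
            f"({r.ba_limits[0]:+.2f}, {r.ba_limits[1]:+.2f})  {r.pct_within_limits:.1f}%"
        )
    c: ClassificationReport = report["classification"]
    lines.append(
        f"type agreement {c.agreement_rate:.2f}%  kappa {c.kappa:.2f}  "
        f"confusion {list(map(list, c.confusion))}"
    )
    return "\n".join(lines)


def report_to_frame(report: dict) -> pd.DataFrame:
    rows = []
    for angle in ("alpha", "beta"):
        row = {"quantity": angle}
        row.update(report[angle].as_dict())
        rows.append(row)
    c = report["classification"]
    rows.append(
        {
            "quantity": "graf_type",
            "agreement_rate": c.agreement_rate,
            "kappa": c.kappa,
        }
    )
    return pd.DataFrame(rows)


def bland_altman_plot(p: PairedAngles, path: str | Path, title: str = "") -> None:
    """Standard Bland-Altman scatter with mean and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = np.asarray(p.method_values)
    r = np.asarray(p.reference_values)
    d = m - r
    mean = d.mean()
    sd = d.std(ddof=1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((m + r) / 2.0, d, s=12, alpha=0.7)
    for y, style in ((mean, "-"), (mean + 1.96 * sd, "--"), (mean - 1.96 * sd, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of methods (deg)")
    ax.set_ylabel("difference (deg)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
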