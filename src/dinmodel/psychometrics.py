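"""Psychometric analysis of accuracy-vs-SNR tables.

Digit recognition accuracy as a function of SNR follows a sigmoid with a
chance floor (10% for ten alternatives). Two fixed-asymptote variants are
used: the human fit

    f_human(x) = 0.10 + 0.90 / (1 + exp(-a (x - b)))

and the model fit

    f_model(x) = 0.09 + 0.88 / (1 + exp(-a (x - b)))

with slope a (1/dB) and inflection b (dB) estimated by non-linear least
squares. The speech reception threshold is the SNR at 50% accuracy, computed
by closed-form inversion of the fitted sigmoid. Model curves can be remapped
into human behavioral space with an SNR-dependent scaling factor derived
from the two fits, and 50%-threshold tables across cochlear states, training
paradigms, and cross-validation folds are analyzed with a repeated-measures
style factorial ANOVA in which folds enter as a blocking (random) factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SIGMOID_VARIANTS",
    "SigmoidFit",
    "PsychometricCurve",
    "ConfusionMatrix",
    "fit_sigmoid",
    "snr_at_accuracy",
    "scale_to_human",
    "confusion_stats",
    "threshold_anova",
    "plot_psychometric",
    "plot_confusion",
]

#: (floor, span) asymptote pairs by variant.
SIGMOID_VARIANTS = {"human": (0.10, 0.90), "model": (0.09, 0.88)}


@dataclass(frozen=True)
class SigmoidFit:
    """A fixed-asymptote sigmoid fit of accuracy against SNR."""

    floor: float
    span: float
    a: float          # slope, 1/dB
    b: float          # inflection, dB
    variant: str
    residual: float = 0.0   # sum of squared residuals at the solution

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return self.floor + self.span / (1.0 + np.exp(-self.a * (x - self.b)))


@dataclass
class PsychometricCurve:
    """Mean accuracy vs SNR with across-fold (or across-subject) dispersion."""

    snr_db: np.ndarray
    accuracy: np.ndarray
    sem: np.ndarray | None = None
    n: int = 1

    def __post_init__(self) -> None:
        self.snr_db = np.asarray(self.snr_db, dtype=np.float64)
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        if np.any(np.diff(self.snr_db) <= 0):
            raise ValueError("SNR grid must be strictly increasing")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracy must lie in [0, 1]")

    @classmethod
    def from_fold_table(cls, table: pd.DataFrame) -> "PsychometricCurve":
        """Aggregate a (fold, snr_db, accuracy) table: mean and SEM over folds."""
        g = table.groupby("snr_db")["accuracy"]
        n = int(table["fold"].nunique()) if "fold" in table else 1
        sem = g.std(ddof=1) / np.sqrt(n) if n > 1 else g.mean() * 0.0
        return cls(snr_db=g.mean().index.to_numpy(),
                   accuracy=g.mean().to_numpy(), sem=sem.to_numpy(), n=n)


def fit_sigmoid(curve: PsychometricCurve, variant: str = "model") -> SigmoidFit:
    """Least-squares (a, b) with floor and span fixed by ``variant``.

    Requires at least 4 SNR points and data that actually rise from the
    floor region toward the ceiling; flat-at-chance data leave the
    inflection unidentifiable and are rejected.
    """
    floor, span = SIGMOID_VARIANTS[variant]
    x, y = curve.snr_db, curve.accuracy
    if len(x) < 4:
        raise ValueError("need at least 4 SNR points to fit a sigmoid")
    if y.max() - y.min() < 0.25 * span:
        raise ValueError(
            "accuracy never rises appreciably above its minimum; the sigmoid "
            f"inflection is not identifiable (range {y.max() - y.min():.3f})")

    def f(x, a, b):
        return floor + span / (1.0 + np.exp(-a * (x - b)))

    # initial slope from the steepest empirical segment, inflection at half rise
    half = floor + span / 2.0
    b0 = float(x[np.argmin(np.abs(y - half))])
    (a, b), _ = curve_fit(f, x, y, p0=(0.3, b0),
                          bounds=([1e-4, x.min() - 50.0], [10.0, x.max() + 50.0]),
                          maxfev=20000)
    residual = float(np.sum((f(x, a, b) - y) ** 2))
    return SigmoidFit(floor=floor, span=span, a=float(a), b=float(b),
                      variant=variant, residual=residual)


def snr_at_accuracy(fit: SigmoidFit, target: float = 0.5) -> float:
    """SNR at which the fitted sigmoid reaches ``target`` accuracy.

    Closed form: x = b - ln(span / (target - floor) - 1) / a. Targets at or
    beyond the asymptotes are unreachable and rejected.
    """
    if not (fit.floor < target < fit.floor + fit.span):
        raise ValueError(f"target {target} outside the open range "
                         f"({fit.floor}, {fit.floor + fit.span})")
    return float(fit.b - np.log(fit.span / (target - fit.floor) - 1.0) / fit.a)


def scale_to_human(model_curve: PsychometricCurve, model_fit: SigmoidFit,
                   human_fit: SigmoidFit) -> PsychometricCurve:
    """Remap a model accuracy curve into human behavioral space.

    SNR-dependent multiplicative factor f_human(x) / f_model(x), clipped to
    [0, 1]. Where the model curve equals its own fit, the scaled curve lands
    exactly on the human fit; identical fits leave the curve unchanged.
    """
    factor = human_fit(model_curve.snr_db) / model_fit(model_curve.snr_db)
    scaled = np.clip(model_curve.accuracy * factor, 0.0, 1.0)
    sem = model_curve.sem * factor if model_curve.sem is not None else None
    return PsychometricCurve(snr_db=model_curve.snr_db.copy(), accuracy=scaled,
                             sem=sem, n=model_curve.n)


@dataclass
class ConfusionMatrix:
    """10x10 digit confusion counts with row-normalized percentages."""

    counts: np.ndarray
    snr_db: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (10, 10):
            raise ValueError("confusion matrix must be 10x10")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_predictions(cls, true_digits, predicted_digits,
                         snr_db: float | None = None,
                         source_id: str = "") -> "ConfusionMatrix":
        counts = np.zeros((10, 10), dtype=np.int64)
        np.add.at(counts, (np.asarray(true_digits), np.asarray(predicted_digits)), 1)
        return cls(counts=counts, snr_db=snr_db, source_id=source_id)

    @property
    def percentages(self) -> np.ndarray:
        """Row-normalized percentages; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, 100.0 * self.counts / totals, 0.0)
        return p


def confusion_stats(a: ConfusionMatrix | np.ndarray,
                    b: ConfusionMatrix | np.ndarray) -> tuple[float, np.ndarray]:
    """RMSE between two row-normalized confusion matrices (percentage points)
    plus the first matrix's per-digit accuracy vector (its diagonal).

    Inputs may be :class:`ConfusionMatrix` objects (row-normalized
    internally) or already-normalized percentage arrays; percentage arrays
    whose rows do not sum to 100 are rejected.
    """
    def as_pct(m):
        if isinstance(m, ConfusionMatrix):
            return m.percentages
        m = np.asarray(m, dtype=np.float64)
        sums = m.sum(axis=1)
        if not np.allclose(sums[sums > 0], 100.0, atol=1e-6):
            raise ValueError("rows of a percentage confusion matrix must sum to 100")
        return m

    pa, pb = as_pct(a), as_pct(b)
    if pa.shape != pb.shape:
        raise ValueError("confusion matrices must share a shape")
    rmse = float(np.sqrt(np.mean((pa - pb) ** 2)))
    return rmse, np.diag(pa).copy()


def plot_psychometric(curves: dict, fits: dict | None = None, ax=None,
                      chance: float = 0.1):
    """Accuracy-vs-SNR curves with SEM bands, plus optional sigmoid fits.

    ``curves`` maps label -> PsychometricCurve; ``fits`` maps label ->
    SigmoidFit drawn as a smooth line. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for label, curve in curves.items():
        line, = ax.plot(curve.snr_db, curve.accuracy, "o-", ms=3, label=label)
        if curve.sem is not None:
            ax.fill_between(curve.snr_db, curve.accuracy - curve.sem,
                            curve.accuracy + curve.sem,
                            color=line.get_color(), alpha=0.25, lw=0)
        if fits and label in fits:
            grid = np.linspace(curve.snr_db[0], curve.snr_db[-1], 200)
            ax.plot(grid, fits[label](grid), "--", color=line.get_color(),
                    lw=1)
    ax.axhline(chance, color="gray", ls=":", lw=1, label="chance")
    ax.set_xlabel("SNR (dB)")
    ax.set_ylabel("digit recognition accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return ax


def plot_confusion(matrix: ConfusionMatrix, ax=None):
    """Row-normalized confusion heatmap (true digit x predicted digit)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(matrix.percentages, cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(10))
    ax.set_yticks(range(10))
    ax.set_xlabel("predicted digit")
    ax.set_ylabel("true digit")
    title = f"SNR {matrix.snr_db:g} dB" if matrix.snr_db is not None else ""
    if matrix.source_id:
        title = f"{matrix.source_id}  {title}".strip()
    ax.set_title(title, fontsize=9)
    plt.colorbar(im, ax=ax, label="% of row")
    return ax


def threshold_anova(thresholds: pd.DataFrame,
                    factors: tuple = ("audiometric", "anf", "mocr", "paradigm"),
                    value_col: str = "threshold_db",
                    fold_col: str = "fold") -> pd.DataFrame:
    """Factorial ANOVA of 50%-SNR thresholds with folds as a blocking factor.

    ``thresholds`` must be a balanced complete design: every combination of
    the factor levels observed once per fold. Main effects and two-way
    interactions are tested against the residual error after removing the
    fold (random/repeated unit) effect; delegates to statsmodels OLS/anova.

    Returns a table with columns effect, F, p, df_num, df_den.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = thresholds.copy()
    counts = df.groupby([*factors])[value_col].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: every factor cell needs the same "
                         "number of folds")
    main = " + ".join(f"C({f})" for f in factors)
    twoway = " + ".join(f"C({a}):C({b})"
                        for i, a in enumerate(factors) for b in factors[i + 1:])
    formula = f"{value_col} ~ {main} + {twoway} + C({fold_col})"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    for name, row in table.iterrows():
        if name in ("Residual", f"C({fold_col})"):
            continue
        effect = name.replace("C(", "").replace(")", "").replace(":", " x ")
        out.append({"effect": effect, "F": float(row["F"]),
                    "p": float(row["PR(>F)"]), "df_num": float(row["df"]),
                    "df_den": float(table.loc["Residual", "df"])})
    return pd.DataFrame(out)
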