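"""Pilot-style analysis: session summaries, trends, quadratic fit, and
bootstrapped condition contrasts.

The analysis works on per-session means — the unit a trainee experiences a
session at — and deliberately stays within estimation statistics: effects
are reported with percentile-bootstrap 95% confidence intervals, no
hypothesis tests are computed.

Session means exclude warm-up and stale ticks: during warm-up there is no
estimate at all (the logged score is neutral filler), and stale stretches
mean no valid breathing cycle was accepted recently, so including either
would contaminate the mean with values that do not reflect measured
breathing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, SummaryError
from .simulator import WITH_FEEDBACK, WITHOUT_FEEDBACK
from .session import SessionRecord

__all__ = [
    "SessionSummary",
    "QuadFit",
    "MeanDiff",
    "summarize_session",
    "summaries_frame",
    "fit_quadratic",
    "mean_difference",
    "session_trends",
    "plot_session_trends",
    "plot_quadratic_fit",
    "plot_difference_distribution",
]


@dataclass(frozen=True)
class SessionSummary:
    """Per-session means over ticks with a defined, non-stale rate estimate.

    ``time_in_band`` (fraction of those ticks with the rate inside the
    target band) is carried as an auxiliary column alongside the primary
    tick-mean of the instantaneous score.
    """

    participant_id: str
    session_index: int
    condition: str
    mean_rate: float
    mean_score: float
    time_in_band: float
    n_ticks_used: int


def summarize_session(record: SessionRecord) -> SessionSummary:
    """Collapse a session record to its per-session means.

    Raises SummaryError when the record contains no defined, non-stale
    rate estimate (nothing measurable happened).
    """
    frame = record.frame
    mask = frame["rate"].notna().to_numpy() & (frame["stale"].to_numpy() == 0)
    if not mask.any():
        raise SummaryError("session record has no defined, non-stale rate estimates")
    rate = frame["rate"].to_numpy()[mask]
    score = frame["score"].to_numpy()[mask]
    band = record.config.band
    return SessionSummary(
        participant_id=record.config.participant_id,
        session_index=record.config.session_index,
        condition=record.config.condition,
        mean_rate=float(rate.mean()),
        mean_score=float(score.mean()),
        time_in_band=float(np.mean((rate >= band.low) & (rate <= band.high))),
        n_ticks_used=int(mask.sum()),
    )


def summaries_frame(summaries) -> pd.DataFrame:
    """Normalize a list of SessionSummary (or an equivalent DataFrame)."""
    if isinstance(summaries, pd.DataFrame):
        return summaries.copy()
    return pd.DataFrame([s.__dict__ for s in summaries])


# ---------------------------------------------------------------------------
# Quadratic fit of mean score on mean rate


@dataclass(frozen=True)
class QuadFit:
    """OLS quadratic fit with a case-resampling bootstrap prediction band."""

    coefficients: tuple[float, float, float]  # (a2, a1, a0), highest power first
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int
    seed: int

    def predict(self, x):
        a2, a1, a0 = self.coefficients
        x = np.asarray(x, dtype=float)
        out = a2 * x**2 + a1 * x + a0
        return float(out) if out.ndim == 0 else out


def _boot_quad_coeffs(x, y, n_boot, rng):
    """Vectorized degree-2 refits on case resamples via batched normal equations.

    Resamples with fewer than three distinct x values cannot identify a
    quadratic and are redrawn.
    """
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    for _ in range(100):
        xs = np.sort(x[idx], axis=1)
        degenerate = (np.diff(xs, axis=1) > 0).sum(axis=1) < 2
        if not degenerate.any():
            break
        idx[degenerate] = rng.integers(0, n, size=(int(degenerate.sum()), n))
    xb, yb = x[idx], y[idx]
    design = np.stack([xb**2, xb, np.ones_like(xb)], axis=2)  # (B, n, 3)
    gram = np.einsum("bni,bnj->bij", design, design)
    rhs = np.einsum("bni,bn->bi", design, yb)
    return np.linalg.solve(gram, rhs[..., None])[..., 0]  # (B, 3)


def fit_quadratic(summaries, n_boot: int = 5000, seed: int | None = None,
                  grid_points: int = 100) -> QuadFit:
    """Fit mean_score ~ a2*mean_rate^2 + a1*mean_rate + a0 by OLS.

    The 95% band is a pointwise percentile interval of the predictions of
    case-resampled refits, evaluated on an equally spaced grid over the
    observed rate range, then widened (if ever needed) to contain the point
    prediction so lower <= prediction <= upper holds everywhere.
    """
    if seed is None:
        raise DesignError("fit_quadratic requires an explicit seed")
    frame = summaries_frame(summaries)
    x = frame["mean_rate"].to_numpy(dtype=float)
    y = frame["mean_score"].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise DesignError("quadratic fit needs >= 3 distinct mean_rate values")

    coeffs = np.polyfit(x, y, 2)
    grid = np.linspace(x.min(), x.max(), grid_points)

    rng = np.random.default_rng(seed)
    boot = _boot_quad_coeffs(x, y, n_boot, rng)
    preds = boot[:, [0]] * grid**2 + boot[:, [1]] * grid + boot[:, [2]]
    lower = np.percentile(preds, 2.5, axis=0)
    upper = np.percentile(preds, 97.5, axis=0)
    point = coeffs[0] * grid**2 + coeffs[1] * grid + coeffs[2]
    return QuadFit(
        coefficients=(float(coeffs[0]), float(coeffs[1]), float(coeffs[2])),
        grid=grid,
        lower=np.minimum(lower, point),
        upper=np.maximum(upper, point),
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Condition contrast


@dataclass(frozen=True)
class MeanDiff:
    """Mean difference (with_feedback - without_feedback) and its bootstrap CI."""

    variable: str
    effect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    pairing: str


def mean_difference(summaries, variable: str = "mean_rate",
                    pairing: str = "by_participant",
                    n_boot: int = 5000, seed: int | None = None) -> MeanDiff:
    """Percentile-bootstrap 95% CI for the condition difference of a variable.

    Paired (default): each participant contributes the difference of their
    condition means; participants are resampled with replacement.  Unpaired:
    each condition's sessions are resampled independently.
    """
    if seed is None:
        raise DesignError("mean_difference requires an explicit seed")
    if pairing not in ("by_participant", "unpaired"):
        raise DesignError(f"unknown pairing {pairing!r}")
    frame = summaries_frame(summaries)
    if variable not in frame.columns:
        raise DesignError(f"unknown variable {variable!r}")
    present = set(frame["condition"])
    for cond in (WITH_FEEDBACK, WITHOUT_FEEDBACK):
        if cond not in present:
            raise DesignError(f"condition {cond!r} missing from the summaries")

    rng = np.random.default_rng(seed)
    if pairing == "by_participant":
        per = frame.groupby(["participant_id", "condition"])[variable].mean().unstack()
        if per[[WITH_FEEDBACK, WITHOUT_FEEDBACK]].isna().any().any():
            raise DesignError("paired analysis requires both conditions per participant")
        diffs = (per[WITH_FEEDBACK] - per[WITHOUT_FEEDBACK]).to_numpy(dtype=float)
        effect = float(diffs.mean())
        idx = rng.integers(0, diffs.size, size=(n_boot, diffs.size))
        stats = diffs[idx].mean(axis=1)
    else:
        a = frame.loc[frame["condition"] == WITH_FEEDBACK, variable].to_numpy(dtype=float)
        b = frame.loc[frame["condition"] == WITHOUT_FEEDBACK, variable].to_numpy(dtype=float)
        effect = float(a.mean() - b.mean())
        ia = rng.integers(0, a.size, size=(n_boot, a.size))
        ib = rng.integers(0, b.size, size=(n_boot, b.size))
        stats = a[ia].mean(axis=1) - b[ib].mean(axis=1)

    ci_low = float(np.percentile(stats, 2.5))
    ci_high = float(np.percentile(stats, 97.5))
    return MeanDiff(
        variable=variable,
        effect=effect,
        ci_low=min(ci_low, effect),
        ci_high=max(ci_high, effect),
        n_boot=n_boot, seed=seed, pairing=pairing,
    )


def session_trends(summaries) -> pd.DataFrame:
    """Tidy long-format table of per-participant and per-session-group means.

    ``level`` is "participant" for individual trajectories and "group" for
    the across-participant mean of each session; no smoothing is applied.
    """
    frame = summaries_frame(summaries)
    if frame.empty:
        raise DesignError("no summaries to tabulate")
    cols = ["participant_id", "session_index", "condition", "mean_rate", "mean_score"]
    per = frame[cols].copy()
    per.insert(0, "level", "participant")
    group = (frame.groupby(["session_index", "condition"], as_index=False)
             [["mean_rate", "mean_score"]].mean())
    group.insert(0, "level", "group")
    group.insert(1, "participant_id", "all")
    out = pd.concat([per, group[per.columns.tolist()[:1] + cols]], ignore_index=True)
    return out.sort_values(["level", "participant_id", "session_index"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Plots (optional; Fig-2/3-style views of the same tables)


def plot_session_trends(trends: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
    for pid, sub in trends[trends["level"] == "participant"].groupby("participant_id"):
        axes[0].plot(sub["session_index"], sub["mean_rate"], alpha=0.4, lw=1)
        axes[1].plot(sub["session_index"], sub["mean_score"], alpha=0.4, lw=1)
    grp = trends[trends["level"] == "group"].groupby("session_index")[
        ["mean_rate", "mean_score"]].mean()
    axes[0].plot(grp.index, grp["mean_rate"], "k-o", lw=2, label="group mean")
    axes[1].plot(grp.index, grp["mean_score"], "k-o", lw=2)
    axes[0].set_ylabel("mean rate (breaths/min)")
    axes[1].set_ylabel("mean score")
    axes[1].set_xlabel("session")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_difference_distribution(summaries, variable: str, path,
                                 pairing: str = "by_participant",
                                 n_boot: int = 5000, seed: int = 0) -> None:
    """Histogram of the bootstrap distribution of the condition difference,
    with the point effect and the 95% percentile interval marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    md = mean_difference(summaries, variable, pairing=pairing, n_boot=n_boot, seed=seed)
    frame = summaries_frame(summaries)
    rng = np.random.default_rng(seed)  # same seed/order as mean_difference
    if pairing == "by_participant":
        per = frame.groupby(["participant_id", "condition"])[variable].mean().unstack()
        diffs = (per[WITH_FEEDBACK] - per[WITHOUT_FEEDBACK]).to_numpy(dtype=float)
        idx = rng.integers(0, diffs.size, size=(n_boot, diffs.size))
        stats = diffs[idx].mean(axis=1)
    else:
        a = frame.loc[frame["condition"] == WITH_FEEDBACK, variable].to_numpy(dtype=float)
        b = frame.loc[frame["condition"] == WITHOUT_FEEDBACK, variable].to_numpy(dtype=float)
        ia = rng.integers(0, a.size, size=(n_boot, a.size))
        ib = rng.integers(0, b.size, size=(n_boot, b.size))
        stats = a[ia].mean(axis=1) - b[ib].mean(axis=1)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(stats, bins=40, alpha=0.6)
    ax.axvline(md.effect, color="k", lw=2, label=f"effect {md.effect:+.3f}")
    for bound in (md.ci_low, md.ci_high):
        ax.axvline(bound, color="k", lw=1, ls="--")
    ax.set_xlabel(f"{variable}: with - without")
    ax.set_ylabel("bootstrap resamples")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_quadratic_fit(fit: QuadFit, summaries, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = summaries_frame(summaries)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.fill_between(fit.grid, fit.lower, fit.upper, alpha=0.3, label="95% bootstrap band")
    ax.plot(fit.grid, fit.predict(fit.grid), "k-", label="quadratic fit")
    ax.plot(frame["mean_rate"], frame["mean_score"], "o", ms=4, alpha=0.6)
    ax.set_xlabel("session mean rate (breaths/min)")
    ax.set_ylabel("session mean score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
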