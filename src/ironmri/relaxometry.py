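"""Mono-exponential T2* estimation with automated echo truncation.

The signal model is ``y(TE) = K * exp(-TE / T2*)``: magnitude signal decays
exponentially with echo time, faster where tissue iron is higher.  At long
TE the measured magnitude flattens onto the rectified-noise floor instead
of reaching zero; fitting those plateau echoes biases T2* upward, which is
why severe iron overload is the regime where naive fits misgrade patients.
The :class:`TruncationPolicy` implements the automated remedy: drop the
longest-TE echo and refit while the goodness of fit stays below a
threshold.

Usage follows the model/results idiom::

    model = MonoExponentialDecayModel(tes, signals)
    res = model.fit(truncation=TruncationPolicy())
    print(res.summary())
    res.plot()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import EchoSeries, EchoTrain, ImageStack
from .exceptions import DegenerateFitError, InvalidInputError

__all__ = [
    "MonoExponentialDecayModel",
    "T2StarFitResults",
    "TruncationPolicy",
    "fit_monoexp",
    "truncated_fit",
    "roi_mean_series",
]

logger = logging.getLogger(__name__)


def _monoexp(te, K, t2star):
    return K * np.exp(-te / t2star)


@dataclass(frozen=True)
class TruncationPolicy:
    """Automated late-echo truncation rule.

    While the current fit's r-squared is below ``r2_threshold`` and at
    least ``min_echoes`` would remain and fewer than ``max_drop`` echoes
    have been removed, drop the longest-TE echo and refit.  ``max_drop``
    of ``None`` means "down to min_echoes".

    With ``improvement_gated`` (the default) a drop is only kept when it
    raises r-squared.  A noise-floor plateau lifts r-squared sharply at
    every removal, so truncation proceeds; ordinary channel noise on a
    shallow decay does not, so clean-but-noisy slow decays are left alone
    instead of being eroded to a 3-point fit.  Set it to False for the
    unconditional threshold rule.

    The default threshold 0.995 keeps clean decays untouched while any
    appreciable late-echo plateau triggers truncation.
    """

    r2_threshold: float = 0.995
    min_echoes: int = 3
    max_drop: int | None = None
    improvement_gated: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise InvalidInputError("r2_threshold must be in (0, 1]")
        if self.min_echoes < 3:
            raise InvalidInputError("min_echoes must be >= 3")
        if self.max_drop is not None and self.max_drop < 0:
            raise InvalidInputError("max_drop must be >= 0")


class T2StarFitResults:
    """Results of one mono-exponential fit.

    Attributes
    ----------
    K, t2star : float
        Amplitude (a.u.) and relaxation time (ms) estimates.
    K_se, t2star_se : float
        Asymptotic standard errors from the nonlinear least-squares
        covariance (``nan`` when the covariance is unavailable).
    rsquared : float
        Coefficient of determination on the signal scale, computed over
        the echoes actually used.
    n_echoes_used, n_echoes_total : int
    truncated : bool
        True iff late echoes were dropped (n_echoes_used < n_echoes_total).
    converged : bool
        False when the nonlinear optimizer failed and the log-linear
        estimate was returned instead.
    """

    def __init__(self, *, K, t2star, K_se, t2star_se, rsquared,
                 n_echoes_used, n_echoes_total, converged, model):
        self.K = float(K)
        self.t2star = float(t2star)
        self.K_se = float(K_se)
        self.t2star_se = float(t2star_se)
        self.rsquared = float(rsquared)
        self.n_echoes_used = int(n_echoes_used)
        self.n_echoes_total = int(n_echoes_total)
        self.converged = bool(converged)
        self.model = model

    @property
    def truncated(self) -> bool:
        return self.n_echoes_used < self.n_echoes_total

    @property
    def r2star(self) -> float:
        """Relaxation rate 1000 / T2* in 1/s (convenience, not reported)."""
        return 1000.0 / self.t2star

    def predict(self, tes=None) -> np.ndarray:
        """Fitted decay K * exp(-TE/T2*) at the given (default: model) TEs."""
        tes = self.model.tes if tes is None else np.asarray(tes, float)
        return _monoexp(tes, self.K, self.t2star)

    def to_dict(self) -> dict:
        return {
            "K": self.K, "t2star_ms": self.t2star,
            "K_se": self.K_se, "t2star_se_ms": self.t2star_se,
            "rsquared": self.rsquared,
            "n_echoes_used": self.n_echoes_used,
            "n_echoes_total": self.n_echoes_total,
            "truncated": self.truncated, "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            "Mono-exponential T2* fit",
            "========================",
            f"T2*        {self.t2star:10.4f} ms   (SE {self.t2star_se:.4f})",
            f"K          {self.K:10.4f} a.u. (SE {self.K_se:.4f})",
            f"R2*        {self.r2star:10.4f} 1/s",
            f"r-squared  {self.rsquared:10.6f}",
            f"echoes     {self.n_echoes_used} of {self.n_echoes_total} used"
            + ("  [truncated]" if self.truncated else ""),
        ]
        if not self.converged:
            lines.append("WARNING: optimizer did not converge; "
                         "log-linear estimate reported")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<T2StarFitResults t2star={self.t2star:.4g} ms K={self.K:.4g} "
                f"r2={self.rsquared:.4f} echoes={self.n_echoes_used}/"
                f"{self.n_echoes_total}>")

    def plot(self, ax=None):
        """Decay scatter with fitted trendline; truncation point marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tes = self.model.tes
        ax.plot(tes, self.model.signals, "o", color="k", label="measured")
        fine = np.linspace(0, tes[-1] * 1.05, 200)
        ax.plot(fine, self.predict(fine), "-", color="tab:red",
                label=f"fit: T2* = {self.t2star:.2f} ms")
        if self.truncated:
            cut = tes[self.n_echoes_used - 1]
            ax.axvline(cut, ls="--", color="tab:gray",
                       label=f"truncated after TE = {cut:g} ms")
            ax.plot(tes[self.n_echoes_used:], self.model.signals[self.n_echoes_used:],
                    "x", color="tab:gray")
        ax.set_xlabel("TE (ms)")
        ax.set_ylabel("signal (a.u.)")
        ax.legend()
        return ax


class MonoExponentialDecayModel:
    """Two-parameter exponential decay model for one echo series.

    Estimation is nonlinear least squares on the signal scale, initialised
    from an ordinary least-squares line fit of ``ln(y)`` against TE over
    the strictly positive signals.  The log fit alone would over-weight
    the low-signal (high-TE) echoes, so it only seeds the optimizer.
    """

    def __init__(self, tes, signals):
        if isinstance(tes, EchoTrain):
            tes = tes.tes
        tes = np.asarray(tes, float)
        signals = np.asarray(signals, float)
        if tes.shape != signals.shape:
            raise InvalidInputError("tes and signals must have the same length")
        series = EchoSeries(EchoTrain(tes), signals)  # validates both
        self.series = series
        self.tes = series.tes
        self.signals = series.signals

    @classmethod
    def from_series(cls, series: EchoSeries) -> "MonoExponentialDecayModel":
        return cls(series.echo_train, series.signals)

    @classmethod
    def from_dataframe(cls, df, te_col: str = "te_ms",
                       signal_col: str = "signal") -> "MonoExponentialDecayModel":
        return cls(df[te_col].to_numpy(), df[signal_col].to_numpy())

    # -- estimation ---------------------------------------------------------

    def _loglinear_start(self, tes, signals):
        pos = signals > 0
        if pos.sum() < 3:
            raise InvalidInputError(
                "need at least 3 strictly positive signals for the fit"
            )
        slope, intercept = np.polyfit(tes[pos], np.log(signals[pos]), 1)
        if slope >= 0:
            raise DegenerateFitError(
                "signal does not decay (log-linear slope >= 0)"
            )
        return float(np.exp(intercept)), float(-1.0 / slope)

    def _fit_window(self, n_used: int) -> T2StarFitResults:
        tes = self.tes[:n_used]
        signals = self.signals[:n_used]
        K0, t20 = self._loglinear_start(tes, signals)
        converged = True
        K_se = t2_se = np.nan
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                popt, pcov = curve_fit(
                    _monoexp, tes, signals, p0=[K0, t20], maxfev=2000,
                )
            K, t2 = float(popt[0]), float(popt[1])
            if K <= 0 or t2 <= 0 or not np.all(np.isfinite(popt)):
                raise RuntimeError("optimizer left the admissible region")
            if np.all(np.isfinite(pcov)):
                K_se, t2_se = np.sqrt(np.diag(pcov))
        except RuntimeError as exc:
            logger.warning("nonlinear fit failed (%s); falling back to "
                           "log-linear estimate", exc)
            K, t2 = K0, t20
            converged = False
        resid = signals - _monoexp(tes, K, t2)
        ss_tot = float(np.sum((signals - signals.mean()) ** 2))
        rsq = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        return T2StarFitResults(
            K=K, t2star=t2, K_se=K_se, t2star_se=t2_se, rsquared=rsq,
            n_echoes_used=n_used, n_echoes_total=len(self.tes),
            converged=converged, model=self,
        )

    def fit(self, truncation: TruncationPolicy | None = None) -> T2StarFitResults:
        """Fit the decay; with a policy, iteratively drop late echoes.

        Parameters
        ----------
        truncation : TruncationPolicy, optional
            When given, refit on shorter windows while r-squared stays
            below the policy threshold.

        Raises
        ------
        DegenerateFitError
            If the retained signals do not decay.
        InvalidInputError
            If fewer than 3 positive signals remain, or the policy wants
            more echoes than exist.
        """
        n = len(self.tes)
        if truncation is None:
            return self._fit_window(n)
        if truncation.min_echoes > n:
            raise InvalidInputError(
                f"policy requires >= {truncation.min_echoes} echoes, "
                f"series has {n}"
            )
        max_drop = n - truncation.min_echoes
        if truncation.max_drop is not None:
            max_drop = min(max_drop, truncation.max_drop)
        res = self._fit_window(n)
        drops = 0
        while (res.rsquared < truncation.r2_threshold
               and drops < max_drop):
            drops += 1
            try:
                cand = self._fit_window(n - drops)
            except (DegenerateFitError, InvalidInputError):
                # shorter window no longer supports a fit; keep the last one
                logger.debug("truncation stopped early at %d echoes",
                             n - drops + 1)
                break
            if truncation.improvement_gated and cand.rsquared <= res.rsquared:
                break
            res = cand
        return res


# -- functional façade ------------------------------------------------------

def fit_monoexp(series: EchoSeries) -> T2StarFitResults:
    """Least-squares mono-exponential fit of one echo series (no truncation)."""
    return MonoExponentialDecayModel.from_series(series).fit()


def truncated_fit(series: EchoSeries,
                  policy: TruncationPolicy | None = None) -> T2StarFitResults:
    """Fit with automated late-echo truncation (default policy if none given)."""
    return MonoExponentialDecayModel.from_series(series).fit(
        truncation=policy or TruncationPolicy()
    )


def roi_mean_series(stack: ImageStack, mask: np.ndarray) -> EchoSeries:
    """Per-echo arithmetic mean of in-mask pixels.

    This is the ROI-based route: average the signal first, fit once.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.spatial_shape:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match stack {stack.spatial_shape}"
        )
    if not mask.any():
        raise InvalidInputError("ROI mask is empty")
    means = stack.data[mask].mean(axis=0)
    return EchoSeries(stack.echo_train, means)
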