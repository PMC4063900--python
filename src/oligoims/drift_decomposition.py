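"""Shared-center Gaussian decomposition of drift-time profiles.

Cross-linking does not create a new set of conformers so much as it shifts
population between the conformers that already exist: the drift-time
profiles of one species measured before and after the reaction can be fit
with a single set of Gaussian components — common centers (and, by default,
common widths) — whose amplitudes alone differ between the two conditions.
The per-condition component area fractions then quantify the
compact <-> extended population shift.

The fit is solved by variable projection: the nonlinear parameters
(centers, widths) are optimized by seeded multi-start least squares, while
for each trial the non-negative amplitudes of every condition are the exact
NNLS solution. Conditions are weighted equally in the objective regardless
of their total intensity, so a dominant condition cannot absorb the shared
parameters.

:class:`SharedGaussianMixture` is a scikit-learn-style estimator
(``fit(t, Y)`` with one intensity column per condition);
:func:`fit_shared_mixture`, :func:`population_shift_report` and
:func:`select_n_components` are the functional surface over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls
from sklearn.base import BaseEstimator

__all__ = [
    "DriftProfile",
    "SharedMixtureFit",
    "SharedGaussianMixture",
    "fit_shared_mixture",
    "population_shift_report",
    "select_n_components",
    "read_profiles",
    "write_fit",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class DriftProfile:
    """A 1-d drift-time profile of one species under one condition."""

    times: np.ndarray  # ms, strictly increasing
    intensities: np.ndarray  # >= 0
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class SharedMixtureFit:
    """Result of a shared-center fit over two (or more) conditions."""

    centers: np.ndarray  # (K,) ms, strictly increasing
    widths: np.ndarray  # (K,) or (n_conditions, K) ms
    amplitudes: np.ndarray  # (n_conditions, K), >= 0
    fractions: np.ndarray  # (n_conditions, K) area fractions; NaN if empty
    residual_rms: np.ndarray  # (n_conditions,)
    conditions: tuple[str, ...]
    ill_conditioned: bool = False


def _design(t: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Unit-height Gaussian design matrix, one column per component."""
    return np.exp(-0.5 * ((t[:, None] - centers[None, :]) / widths[None, :]) ** 2)


class SharedGaussianMixture(BaseEstimator):
    """Gaussian mixture with centers (and optionally widths) shared across conditions.

    Parameters
    ----------
    n_components : int or 'auto'
        Number of Gaussian components; 'auto' selects it by a BIC-style
        penalized residual over ``1..n_max`` (smallest n within 1% of the
        best score).
    n_max : int
        Search ceiling for 'auto'.
    tie_widths : bool
        Share widths across conditions as well as centers (default); with
        False only centers are shared and each condition gets its own widths.
    share_centers : bool
        With False the conditions are fit completely independently —
        the unconstrained reference against which the shared fit's residual
        can be compared.
    n_starts : int
        Multi-start count for the nonlinear stage; starts are seeded jitters
        of a local-maxima initialization, and ties break toward the lowest
        residual.
    random_state : int
        Seed for the start jitter; fixed seed gives a deterministic fit.

    Attributes (after fit)
    ----------------------
    centers_, widths_, amplitudes_, fractions_, residual_rms_,
    ill_conditioned_, n_components_ : see :class:`SharedMixtureFit`.
    """

    def __init__(
        self,
        n_components: "int | str" = "auto",
        n_max: int = 5,
        tie_widths: bool = True,
        share_centers: bool = True,
        n_starts: int = 10,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_max = n_max
        self.tie_widths = tie_widths
        self.share_centers = share_centers
        self.n_starts = n_starts
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _initial_centers(t: np.ndarray, Y: np.ndarray, k: int) -> np.ndarray:
        """Top-k local maxima of the max-normalized summed profile."""
        y = np.zeros_like(t)
        for col in Y.T:
            peak = col.max()
            if peak > 0:
                y = y + col / peak
        interior = np.arange(1, len(t) - 1)
        is_max = (y[interior] >= y[interior - 1]) & (y[interior] > y[interior + 1])
        cand = interior[is_max]
        cand = cand[np.argsort(y[cand])[::-1]]
        centers = list(t[cand[:k]])
        # pad with quantiles if the profile has fewer maxima than components
        qs = np.linspace(0.2, 0.8, k)
        i = 0
        while len(centers) < k:
            centers.append(float(np.quantile(t, qs[i % k])))
            i += 1
        return np.sort(np.array(centers[:k]))

    def _fit_one_condition_set(self, t, Y, k, rng):
        """Shared-parameter fit of Y's columns with k components."""
        n_cond = Y.shape[1]
        step = float(np.min(np.diff(t)))
        span = float(t[-1] - t[0])
        w_lo, w_hi = step / 2.0, span
        scales = np.array([col.max() if col.max() > 0 else 1.0 for col in Y.T])

        n_w = k if self.tie_widths else k * n_cond

        def unpack(p):
            centers = p[:k]
            widths = p[k:k + n_w]
            if self.tie_widths:
                return centers, np.tile(widths, (n_cond, 1))
            return centers, widths.reshape(n_cond, k)

        def residuals(p):
            centers, widths = unpack(p)
            out = []
            for j in range(n_cond):
                G = _design(t, centers, widths[j])
                amp, _ = nnls(G, Y[:, j])
                out.append((G @ amp - Y[:, j]) / scales[j])
            return np.concatenate(out)

        c0 = self._initial_centers(t, Y, k)
        w0 = np.full(n_w, max(span / (4.0 * k), w_lo * 1.01))
        lb = np.concatenate([np.full(k, t[0]), np.full(n_w, w_lo)])
        ub = np.concatenate([np.full(k, t[-1]), np.full(n_w, w_hi)])

        best = None
        for start in range(self.n_starts):
            centers0 = c0.copy()
            if start > 0:
                centers0 = np.clip(
                    c0 + rng.normal(0.0, max(span / 20.0, step), k), t[0], t[-1]
                )
            p0 = np.clip(np.concatenate([np.sort(centers0), w0]), lb, ub)
            sol = least_squares(residuals, p0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
            cost = 2.0 * sol.cost
            if best is None or cost < best[0] - 1e-15:
                best = (cost, sol)
        if best is None or not np.isfinite(best[0]):
            raise RuntimeError("shared mixture fit failed to converge from any start")
        _, sol = best
        centers, widths = unpack(sol.x)
        order = np.argsort(centers)
        centers = centers[order]
        widths = widths[:, order]

        amplitudes = np.zeros((n_cond, k))
        resid_rms = np.zeros(n_cond)
        for j in range(n_cond):
            G = _design(t, centers, widths[j])
            amp, _ = nnls(G, Y[:, j])
            amplitudes[j] = amp
            resid_rms[j] = float(np.sqrt(np.mean((G @ amp - Y[:, j]) ** 2)))
        return centers, widths, amplitudes, resid_rms

    def _fit_independent(self, t, Y, k, rng):
        """Per-condition fits (share_centers=False): the unconstrained reference."""
        n_cond = Y.shape[1]
        centers = np.zeros((n_cond, k))
        widths = np.zeros((n_cond, k))
        amplitudes = np.zeros((n_cond, k))
        resid_rms = np.zeros(n_cond)
        for j in range(n_cond):
            c, w, a, r = self._fit_one_condition_set(t, Y[:, [j]], k, rng)
            centers[j], widths[j], amplitudes[j], resid_rms[j] = c, w[0], a[0], r[0]
        self.centers_per_condition_ = centers
        return centers[0], widths, amplitudes, resid_rms

    @staticmethod
    def _bic(Y: np.ndarray, resid_rms: np.ndarray, n_params: int) -> float:
        n_obs = Y.size
        rss = float(np.sum(resid_rms ** 2 * Y.shape[0]))
        scale = float(np.max(Y) ** 2) if np.max(Y) > 0 else 1.0
        rss = max(rss, 1e-12 * scale * n_obs)  # floor: near-perfect fits tie
        return n_obs * np.log(rss / n_obs) + n_params * np.log(n_obs)

    def _n_params(self, k: int, n_cond: int) -> int:
        widths = k if self.tie_widths else k * n_cond
        return k + widths + k * n_cond  # centers + widths + amplitudes

    # -- API ---------------------------------------------------------------

    def fit(self, t, Y):
        """Fit the mixture to ``Y`` (n_times, n_conditions) sampled at ``t``."""
        t = np.asarray(t, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if t.ndim != 1 or Y.shape[0] != len(t):
            raise ValueError("t must be 1-d and match Y's first dimension")
        if len(t) < 4:
            raise ValueError("need at least 4 samples")
        if np.any(Y < 0):
            raise ValueError("intensities must be non-negative")
        n_cond = Y.shape[1]
        rng = np.random.default_rng(self.random_state)

        if self.n_components == "auto":
            k, bic_path = self._select(t, Y, rng)
            self.bic_path_ = bic_path
        else:
            k = int(self.n_components)
            if k < 1:
                raise ValueError("n_components must be >= 1")

        fit_fn = self._fit_one_condition_set if self.share_centers else self._fit_independent
        centers, widths, amplitudes, resid_rms = fit_fn(t, Y, k, rng)

        # area of a Gaussian component = amplitude * width * sqrt(2 pi)
        areas = amplitudes * widths * _SQRT2PI
        fractions = np.full_like(areas, np.nan)
        for j in range(n_cond):
            tot = areas[j].sum()
            if tot > 0:
                fractions[j] = areas[j] / tot

        peak_scale = max(float(Y.max()), 1e-300)
        rel_rms = resid_rms / peak_scale
        # R^2 against per-condition means, pooled
        ss_res = float(np.sum(resid_rms ** 2 * Y.shape[0]))
        ss_tot = float(np.sum((Y - Y.mean(axis=0, keepdims=True)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        crowded = bool(
            k > 1 and np.any(np.diff(centers) < np.minimum(widths[0][1:], widths[0][:-1]))
        )
        self.ill_conditioned_ = bool(r2 < 0.2 or crowded)

        self.n_components_ = k
        self.centers_ = centers
        self.widths_ = widths[0] if self.tie_widths else widths
        self.amplitudes_ = amplitudes
        self.fractions_ = fractions
        self.residual_rms_ = resid_rms
        self.relative_rms_ = rel_rms
        self.r2_ = r2
        return self

    def _select(self, t, Y, rng):
        """Smallest k whose BIC is within 1% of the best over 1..n_max."""
        bics = []
        for k in range(1, self.n_max + 1):
            try:
                _, _, _, resid_rms = self._fit_one_condition_set(t, Y, k, rng)
            except RuntimeError:
                bics.append(np.inf)
                continue
            bics.append(self._bic(Y, resid_rms, self._n_params(k, Y.shape[1])))
        bics = np.asarray(bics)
        best = float(np.min(bics))
        tol = 0.01 * abs(best)
        k = 1 + int(np.argmax(bics <= best + tol))
        return k, bics

    def to_fit(self, conditions: tuple[str, ...] = ()) -> SharedMixtureFit:
        if not hasattr(self, "centers_"):
            raise RuntimeError("estimator is not fitted")
        n_cond = self.amplitudes_.shape[0]
        if not conditions:
            conditions = tuple(f"condition{j}" for j in range(n_cond))
        widths = self.widths_
        return SharedMixtureFit(
            centers=self.centers_.copy(),
            widths=np.asarray(widths).copy(),
            amplitudes=self.amplitudes_.copy(),
            fractions=self.fractions_.copy(),
            residual_rms=self.residual_rms_.copy(),
            conditions=conditions,
            ill_conditioned=self.ill_conditioned_,
        )


def fit_shared_mixture(
    profile_before: DriftProfile,
    profile_after: DriftProfile,
    n_components: "int | str" = "auto",
    tie_widths: bool = True,
    n_starts: int = 10,
    random_state: int = 0,
    n_max: int = 5,
) -> SharedMixtureFit:
    """Fit one shared set of Gaussians to a before/after profile pair."""
    if profile_before.times.shape != profile_after.times.shape or not np.allclose(
        profile_before.times, profile_after.times
    ):
        raise ValueError("before/after profiles must share the same drift grid")
    est = SharedGaussianMixture(
        n_components=n_components, tie_widths=tie_widths,
        n_starts=n_starts, random_state=random_state, n_max=n_max,
    )
    Y = np.column_stack([profile_before.intensities, profile_after.intensities])
    est.fit(profile_before.times, Y)
    return est.to_fit(
        (profile_before.condition or "before", profile_after.condition or "after")
    )


def population_shift_report(fit: SharedMixtureFit) -> pd.DataFrame:
    """Per-component population-shift table.

    Columns: center, width, fraction per condition, delta_fraction
    (last condition minus first) and a direction label; the frame's
    ``attrs['shift_direction']`` summarizes whether the population moved
    toward the compact (small drift time, small cross-section) or the
    extended end of the profile.
    """
    widths = np.atleast_2d(fit.widths)[0]
    frac0, frac1 = fit.fractions[0], fit.fractions[-1]
    delta = frac1 - frac0
    rows = pd.DataFrame(
        {
            "center_ms": fit.centers,
            "width_ms": widths,
            f"fraction_{fit.conditions[0]}": frac0,
            f"fraction_{fit.conditions[-1]}": frac1,
            "delta_fraction": delta,
            "direction": [
                "gains" if d > 0 else ("loses" if d < 0 else "unchanged")
                for d in np.nan_to_num(delta)
            ],
        }
    )
    if np.all(np.isfinite(frac0)) and np.all(np.isfinite(frac1)):
        mean0 = float(np.dot(fit.centers, frac0))
        mean1 = float(np.dot(fit.centers, frac1))
        if mean1 < mean0 - 1e-12:
            rows.attrs["shift_direction"] = "toward compact"
        elif mean1 > mean0 + 1e-12:
            rows.attrs["shift_direction"] = "toward extended"
        else:
            rows.attrs["shift_direction"] = "none"
    else:
        rows.attrs["shift_direction"] = "undefined"
    return rows


def select_n_components(
    profile_before: DriftProfile,
    profile_after: DriftProfile,
    n_max: int = 5,
    random_state: int = 0,
) -> int:
    """Number of shared components chosen by the penalized-residual rule."""
    est = SharedGaussianMixture(n_components="auto", n_max=n_max, random_state=random_state)
    Y = np.column_stack([profile_before.intensities, profile_after.intensities])
    est.fit(profile_before.times, Y)
    return est.n_components_


def read_profiles(path) -> dict[str, DriftProfile]:
    """Read profiles from CSV columns (drift_ms, intensity, condition)."""
    df = pd.read_csv(path)
    required = {"drift_ms", "intensity", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile CSV needs columns {sorted(required)}")
    out = {}
    for cond, grp in df.groupby("condition"):
        grp = grp.sort_values("drift_ms")
        out[str(cond)] = DriftProfile(
            times=grp["drift_ms"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
            condition=str(cond),
        )
    return out


def write_fit(path, fit: SharedMixtureFit) -> None:
    """Write a fit as JSON: centers, widths, per-condition amplitudes/fractions."""
    payload = {
        "centers_ms": fit.centers.tolist(),
        "widths_ms": np.asarray(fit.widths).tolist(),
        "conditions": list(fit.conditions),
        "amplitudes": fit.amplitudes.tolist(),
        "fractions": np.where(np.isfinite(fit.fractions), fit.fractions, None).tolist(),
        "residual_rms": fit.residual_rms.tolist(),
        "ill_conditioned": fit.ill_conditioned,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
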