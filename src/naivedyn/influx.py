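"""Empirical description of thymic export.

The rate at which naive T cells enter the periphery is taken to be
proportional to the number of late-stage single-positive (SP4/SP8)
thymocytes, with the Ki67-high/low split of new emigrants inherited from
the Ki67+ fraction among those thymocytes.  Both quantities are described
by smooth parametric functions of mouse age:

* ``S(t) = exp(c0) * exp(-nu*t) * (1 - exp(-omega*t))`` — a strictly
  positive double-exponential: rapid neonatal growth on timescale 1/omega,
  slow involution at rate nu.  Fitted by least squares on the log scale.
* ``kappa(t) = k_min + (1 - k_min) / (1 + (t/tau)^h)`` — a decreasing
  logistic in log age, ~1 in neonates and declining to an adult plateau.
  Fitted by nonlinear least squares on the logit scale.

The absolute daily export rate per SP thymocyte, ``psi``, is deliberately
*not* identified here: it multiplies ``S(t)`` and is estimated (or fixed)
downstream.  The descriptor therefore carries shape functions plus a psi
slot.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

AGE_DOMAIN = (1.0, 600.0)  # days of mouse age over which descriptors are valid

__all__ = [
    "InfluxDescriptor",
    "fit_sp_descriptor",
    "influx_rate",
    "AGE_DOMAIN",
    "SP_SCHEMA_COLUMNS",
]

SP_SCHEMA_COLUMNS = ["mouse_age_days", "subset", "sp_count", "sp_ki67_frac"]


class FitConvergenceError(RuntimeError):
    """Raised when a descriptor fit fails to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class InfluxDescriptor:
    """Shape of thymic export vs mouse age.

    count_params: (c0, nu, omega) of S(t) = e^c0 e^{-nu t}(1-e^{-omega t})
    ki67_params:  (k_min, tau, h) of the logistic kappa(t)
    psi:          export rate per SP thymocyte per day; free parameter.
    """

    count_params: tuple = (np.log(3.6e6), 0.0035, 0.06)
    ki67_params: tuple = (0.15, 30.0, 2.5)
    psi: float = 0.07
    subset: str = "CD4"
    family: str = "loglinear-logistic"
    diagnostics: dict = field(default_factory=dict)

    def sp_count(self, t):
        """S(t): late-stage SP thymocyte numbers at mouse age t (days)."""
        t = np.asarray(t, dtype=float)
        c0, nu, omega = self.count_params
        return np.exp(c0 - nu * t) * (-np.expm1(-omega * t))

    def ki67_frac(self, t):
        """kappa(t): Ki67+ fraction among late-stage SP thymocytes."""
        t = np.asarray(t, dtype=float)
        k_min, tau, h = self.ki67_params
        return k_min + (1.0 - k_min) / (1.0 + (t / tau) ** h)

    def total_influx(self, t):
        """psi * S(t): total export in cells/day."""
        return self.psi * self.sp_count(t)

    def to_json(self, path=None):
        payload = {
            "family": self.family,
            "subset": self.subset,
            "count_params": list(self.count_params),
            "ki67_params": list(self.ki67_params),
            "psi": self.psi,
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source):
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            count_params=tuple(payload["count_params"]),
            ki67_params=tuple(payload["ki67_params"]),
            psi=payload["psi"],
            subset=payload.get("subset", "CD4"),
            family=payload.get("family", "loglinear-logistic"),
            diagnostics=payload.get("diagnostics", {}),
        )


def _validate_sp_table(data: pd.DataFrame, subset: str) -> pd.DataFrame:
    rows = data.loc[data["subset"] == subset].copy()
    lo, hi = AGE_DOMAIN
    bad = (rows["mouse_age_days"] < lo) | (rows["mouse_age_days"] > hi)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} SP rows outside the {lo}-{hi} day age domain "
            "were dropped",
            stacklevel=3,
        )
        rows = rows.loc[~bad]
    if len(rows) < 8:
        raise ValueError(
            f"need >= 8 observations for subset {subset!r}, got {len(rows)}"
        )
    ages = rows["mouse_age_days"].to_numpy(float)
    if not (ages.min() < 21.0 and ages.max() > 90.0):
        raise ValueError(
            "SP data must span neonatal (<21 d) and adult (>90 d) ages; "
            f"observed range {ages.min():.0f}-{ages.max():.0f} d"
        )
    return rows


def fit_sp_descriptor(data: pd.DataFrame, subset: str = "CD4") -> InfluxDescriptor:
    """Fit S(t) and kappa(t) to an SP thymocyte timecourse table.

    ``data`` must carry columns ``mouse_age_days, subset, sp_count,
    sp_ki67_frac``.  Counts are fitted on the log scale (linear least
    squares), Ki67 fractions on the logit scale (trust-region nonlinear
    least squares).  ``psi`` is left at its default; it is not identified
    by SP data alone.
    """
    rows = _validate_sp_table(data, subset)
    t = rows["mouse_age_days"].to_numpy(float)
    counts = rows["sp_count"].to_numpy(float)
    if np.any(counts <= 0):
        raise ValueError("sp_count must be positive for log-scale fitting")

    # --- S(t): log-scale least squares on the double-exponential ----------
    logc = np.log(counts)

    def resid_counts(theta):
        c0, lnu, lom = theta
        nu, omega = np.exp(lnu), np.exp(lom)
        return c0 - nu * t + np.log(-np.expm1(-omega * t)) - logc

    best_c = None
    for nu0, om0 in [(0.0035, 0.06), (1e-6, 3.0), (0.01, 0.02)]:
        theta0 = [logc.max(), np.log(nu0), np.log(om0)]
        sol = least_squares(resid_counts, theta0, method="trf", max_nfev=3000)
        if best_c is None or sol.cost < best_c.cost:
            best_c = sol
    c0 = float(best_c.x[0])
    nu = float(np.exp(best_c.x[1]))
    omega = float(np.exp(best_c.x[2]))
    count_rss = float(2 * best_c.cost)

    # --- kappa(t): logit-scale nonlinear least squares --------------------
    k = np.clip(rows["sp_ki67_frac"].to_numpy(float), 1e-6, 1 - 1e-6)
    target = np.log(k / (1 - k))

    def resid(theta):
        k_min = 1 / (1 + np.exp(-theta[0]))  # in (0,1)
        tau = np.exp(theta[1])
        h = np.exp(theta[2])
        pred = k_min + (1 - k_min) / (1 + (t / tau) ** h)
        pred = np.clip(pred, 1e-9, 1 - 1e-9)
        return np.log(pred / (1 - pred)) - target

    best = None
    for tau0, h0 in [(30.0, 2.5), (60.0, 1.5), (15.0, 4.0)]:
        k_floor = max(min(k.min() * 0.8, 0.5), 1e-3)
        theta0 = [np.log(k_floor / (1 - k_floor)), np.log(tau0), np.log(h0)]
        sol = least_squares(resid, theta0, method="trf", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e3:
        raise FitConvergenceError(
            "kappa(t) fit failed to converge",
            diagnostics={"status": getattr(best, "status", None)},
        )
    k_min = 1 / (1 + np.exp(-best.x[0]))
    tau = float(np.exp(best.x[1]))
    h = float(np.exp(best.x[2]))

    # special-case exactly constant Ki67 data: logistic with h -> 0 is
    # degenerate, so collapse to (k_min=2k-1, h=0) when representable
    if np.allclose(k, k[0]):
        const = float(k[0])
        if const >= 0.5:
            k_min, tau, h = 2 * const - 1.0, 30.0, 0.0

    desc = InfluxDescriptor(
        count_params=(c0, nu, omega),
        ki67_params=(float(k_min), tau, h),
        subset=subset,
        diagnostics={
            "count_rss_log": count_rss,
            "ki67_rss_logit": float(2 * best.cost),
            "n_obs": int(len(rows)),
        },
    )
    # contract: fitted kappa must be monotone non-increasing on [5, 120] d
    grid = np.linspace(5.0, 120.0, 200)
    kk = desc.ki67_frac(grid)
    if np.any(np.diff(kk) > 1e-9):
        raise FitConvergenceError("fitted kappa(t) is not monotone non-increasing")
    return desc


def influx_rate(t, ki67_state: str, d: InfluxDescriptor):
    """Cells/day exported from the thymus in one Ki67 state at mouse age t.

    Ki67+ emigrants arrive at rate psi*S(t)*kappa(t), Ki67- at
    psi*S(t)*(1-kappa(t)); the two always sum to the total export psi*S(t).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < AGE_DOMAIN[0]):
        raise ValueError(f"mouse age must be >= {AGE_DOMAIN[0]} d")
    total = d.total_influx(t)
    kappa = d.ki67_frac(t)
    if ki67_state in ("pos", "+", "ki67pos"):
        return total * kappa
    if ki67_state in ("neg", "-", "ki67neg"):
        return total * (1.0 - kappa)
    raise ValueError(f"unknown ki67_state {ki67_state!r}")


def read_sp_csv(path) -> pd.DataFrame:
    """Read an SP thymocyte timecourse CSV (UTF-8, header required)."""
    df = pd.read_csv(path, encoding="utf-8-sig")
    missing = set(SP_SCHEMA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SP CSV missing columns: {sorted(missing)}")
    return df
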