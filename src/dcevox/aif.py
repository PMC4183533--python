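"""Arterial input function: plasma contrast-agent concentration C_p(t).

The built-in parametric model is a gamma-variate bolus with a delayed
biexponential washout tail, shaped like the population-averaged arterial
curves measured in small-animal DCE-MRI: a sharp first pass peaking at
0.88 min followed by a slow clearance plateau.  A measured AIF can be
substituted from a two-column CSV (time in minutes, concentration in mM).
Internally time is in seconds and concentration in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AIFModel", "parametric_aif", "evaluate_aif", "load_aif", "save_aif_csv"]


@dataclass
class AIFModel:
    """Plasma concentration function, parametric or tabulated.

    Parameters for the parametric kind: ``peak_time_s`` is the bolus peak
    time, ``peak_mM`` the peak plasma concentration, ``bolus_shape`` the
    gamma-variate exponent, ``washout_amps`` / ``washout_rates`` the
    biexponential tail (amplitudes in mM, rates in 1/s) which is ramped in
    smoothly so that C_p(0) = 0 and the bolus peak location is preserved.
    """

    kind: str = "parametric"
    duration: float = 660.0
    # parametric fields
    peak_time_s: float = 52.8
    peak_mM: float = 3.0
    bolus_shape: float = 3.0
    washout_amps: tuple[float, float] = (0.50, 0.30)
    washout_rates: tuple[float, float] = (1.0 / 120.0, 1.0 / 3000.0)
    washout_ramp_s: float = 30.0
    # tabulated fields
    t_s: np.ndarray | None = None
    cp_mM: np.ndarray | None = None
    _amp: float = field(init=False, default=1.0, repr=False)
    _tp: float = field(init=False, default=0.0, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("parametric", "tabulated"):
            raise ValueError(f"unknown AIF kind {self.kind!r}")
        if self.kind == "tabulated":
            t = np.asarray(self.t_s, dtype=float)
            c = np.asarray(self.cp_mM, dtype=float)
            if t.ndim != 1 or t.shape != c.shape or len(t) < 2:
                raise ValueError("tabulated AIF needs matching 1-D t/c arrays")
            if np.any(np.diff(t) <= 0):
                raise ValueError("tabulated AIF times must be strictly increasing")
            if np.any(c < 0):
                raise ValueError("tabulated AIF concentrations must be non-negative")
            self.t_s, self.cp_mM = t, c
            self.duration = float(t[-1])
        else:
            # calibrate the internal bolus peak so that the *total* curve
            # (bolus + rising washout) peaks exactly at peak_time_s, and
            # normalize so its maximum equals peak_mM
            self._tp = self.peak_time_s
            tt = np.arange(0.0, min(self.duration, 4 * self.peak_time_s), 0.01)
            for _ in range(3):
                t_star = tt[int(np.argmax(self._raw(tt)))]
                self._tp -= t_star - self.peak_time_s
            raw = self._raw(tt)
            self._amp = self.peak_mM / raw.max()

    # -- parametric pieces -----------------------------------------------
    def _raw(self, t: np.ndarray) -> np.ndarray:
        tp, a = getattr(self, "_tp", self.peak_time_s), self.bolus_shape
        x = np.maximum(t, 0.0) / tp
        bolus = np.where(t > 0, x**a * np.exp(a * (1.0 - x)), 0.0)
        ramp = 1.0 - np.exp(-((np.maximum(t, 0.0) / self.washout_ramp_s) ** 2))
        tail = ramp * sum(
            A * np.exp(-m * np.maximum(t, 0.0))
            for A, m in zip(self.washout_amps, self.washout_rates)
        )
        return bolus + tail

    def __call__(self, t):
        return evaluate_aif(self, t)


def parametric_aif(**kwargs) -> AIFModel:
    """Convenience constructor for the default parametric AIF."""
    return AIFModel(kind="parametric", **kwargs)


def evaluate_aif(model: AIFModel, t) -> np.ndarray | float:
    """Evaluate C_p(t) in mM for scalar or vector time(s) in seconds.

    Raises
    ------
    ValueError
        If any time lies outside [0, duration].
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < -1e-12) or np.any(tt > model.duration + 1e-9):
        raise ValueError(
            f"time outside [0, {model.duration}] s requested from the AIF"
        )
    if model.kind == "tabulated":
        out = np.interp(tt, model.t_s, model.cp_mM)
    else:
        out = model._amp * model._raw(np.atleast_1d(tt))
        out = out.reshape(tt.shape)
    return float(out) if np.isscalar(t) or tt.ndim == 0 else out


def load_aif(path: str | Path, duration: float | None = None) -> AIFModel:
    """Load a tabulated AIF from a CSV of (time [min], concentration [mM]).

    A single header line is tolerated.  Times must be strictly increasing
    and concentrations non-negative.
    """
    rows = []
    with open(path) as f:
        for ln, line in enumerate(f):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(";", ",").split(",")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if ln == 0:
                    continue  # header
                raise ValueError(f"cannot parse AIF file line {ln + 1}: {line!r}")
    if len(rows) < 2:
        raise ValueError("AIF file needs at least two data rows")
    arr = np.asarray(rows)
    model = AIFModel(kind="tabulated", t_s=arr[:, 0] * 60.0, cp_mM=arr[:, 1])
    if duration is not None:
        model.duration = min(model.duration, duration)
    return model


def save_aif_csv(model: AIFModel, path: str | Path, dt_s: float = 1.0) -> None:
    """Write the AIF as a two-column CSV (t_min, cp_mM)."""
    if model.kind == "tabulated":
        t, c = model.t_s, model.cp_mM
    else:
        t = np.arange(0.0, model.duration + 0.5 * dt_s, dt_s)
        c = evaluate_aif(model, t)
    with open(path, "w") as f:
        f.write("t_min,cp_mM\n")
        for ti, ci in zip(t, c):
            f.write(f"{float(ti) / 60.0!r},{float(ci)!r}\n")
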