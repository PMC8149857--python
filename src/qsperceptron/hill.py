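"""Hill-equation transfer functions for engineered sender and receiver circuits.

Senders are *E. coli* carrying a (possibly mutated) P_lux promoter: the inducer
OC6 activates transcription of ``cinI`` (OHC14 synthase) and mCherry, so the
sender dose-response is an increasing Hill function of OC6.  Receivers carry a
P_cin promoter activated by OHC14 and report EYFP; their activation function is
likewise an increasing Hill curve, either open-loop (OL) or sharpened by
positive feedback (PF).  A P_lux *repressor* promoter realises a negative
perceptron weight and follows the decreasing Hill form.

Activator form::

    f(x) = beta_m * (x/K_d)^n / (1 + (x/K_d)^n) + beta_m * beta_0

Repressor form::

    f(x) = alpha_m / (1 + (x/K_d)^n) + alpha_0 * alpha_m
         = alpha_hat_m * ((x/K_d)^n/(1+(x/K_d)^n) - alpha_0 - 1),  alpha_hat_m = -alpha_m

``beta_m`` (maximal promoter activity) is the quantity factored out as the
perceptron weight for activator senders; ``alpha_hat_m = -alpha_m`` is the
signed weight of the repressor sender.

The module ships a registry of the fitted parameters for the eight measured
circuits and least-squares fitting of new dose-response tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger("qsperceptron")

__all__ = [
    "HillActivatorParams",
    "HillRepressorParams",
    "DoseResponse",
    "FitResult",
    "default_registry",
    "eval_activator",
    "eval_repressor",
    "fit_activator",
    "fit_repressor",
    "hill_fraction",
    "load_registry",
    "save_registry",
    "UNIT_UM",
    "UNIT_MCHERRY",
]

#: input-axis units used in the registry
UNIT_UM = "uM"
UNIT_MCHERRY = "mCherry_au"

# fits flagged as poor when RMS log10 residual exceeds this (~26% typical deviation)
POOR_FIT_RMS_LOG10 = 0.1
# flat-response guard: max/min response ratio below this makes n unidentifiable
FLAT_RESPONSE_RATIO = 1.05
N_BOUNDS = (0.1, 10.0)
MIN_DISTINCT_LEVELS = 4


@dataclass(frozen=True)
class HillActivatorParams:
    """Parameters of an increasing Hill transfer function.

    ``K_d`` shares the unit of the input axis (``input_unit``); ``beta_m`` is in
    fluorescence arbitrary units; ``n`` and ``beta_0`` are dimensionless.
    """

    K_d: float
    n: float
    beta_m: float
    beta_0: float
    label: str = ""
    input_unit: str = UNIT_UM

    def __post_init__(self) -> None:
        if not (self.K_d > 0 and self.n > 0 and self.beta_m > 0 and self.beta_0 >= 0):
            raise ValueError(
                f"invalid activator parameters for {self.label!r}: "
                f"K_d={self.K_d}, n={self.n}, beta_m={self.beta_m}, beta_0={self.beta_0}"
            )

    @property
    def basal(self) -> float:
        """Output at zero input, beta_m * beta_0."""
        return self.beta_m * self.beta_0

    @property
    def saturation(self) -> float:
        """Supremum of the output, beta_m * (1 + beta_0)."""
        return self.beta_m * (1.0 + self.beta_0)

    @property
    def span(self) -> float:
        """Dynamic range saturation - basal = beta_m."""
        return self.beta_m


@dataclass(frozen=True)
class HillRepressorParams:
    """Parameters of a decreasing Hill transfer function (P_lux repressor)."""

    K_d: float
    n: float
    alpha_m: float
    alpha_0: float
    label: str = ""
    input_unit: str = UNIT_UM

    def __post_init__(self) -> None:
        if not (self.K_d > 0 and self.n > 0 and self.alpha_m > 0 and self.alpha_0 >= 0):
            raise ValueError(
                f"invalid repressor parameters for {self.label!r}: "
                f"K_d={self.K_d}, n={self.n}, alpha_m={self.alpha_m}, alpha_0={self.alpha_0}"
            )

    @property
    def alpha_hat_m(self) -> float:
        """Signed perceptron weight of the repressor promoter (negative)."""
        return -self.alpha_m

    @property
    def floor(self) -> float:
        """Limit as x -> inf, alpha_0 * alpha_m."""
        return self.alpha_0 * self.alpha_m

    @property
    def ceiling(self) -> float:
        """Output at zero input, alpha_m * (1 + alpha_0)."""
        return self.alpha_m * (1.0 + self.alpha_0)


HillParams = Union[HillActivatorParams, HillRepressorParams]


def default_registry() -> dict[str, HillParams]:
    """The eight fitted circuit parameterizations shipped with the package.

    R_PF / R_OL: receiver EYFP vs OHC14 (uM), positive-feedback and open-loop.
    S_mut40/7/8/15: mutated P_lux activator senders, mCherry vs OC6 (uM).
    S_plux_rep: P_lux repressor sender, mCherry vs OC6 (uM).
    R_mCh: receiver EYFP vs sender mCherry level (arb. units) -- the empirical
    activation function sigma of the consortium perceptron.
    """
    return {
        "R_PF": HillActivatorParams(0.28, 1.97, 2.25e4, 3.95e-2, "R_PF", UNIT_UM),
        "R_OL": HillActivatorParams(3.41, 0.809, 2.57e4, 7.23e-3, "R_OL", UNIT_UM),
        "S_mut40": HillActivatorParams(15.0, 0.352, 5521.0, 4.95e-3, "S_mut40", UNIT_UM),
        "S_mut7": HillActivatorParams(50.0, 0.482, 1906.0, 9.1e-2, "S_mut7", UNIT_UM),
        "S_mut8": HillActivatorParams(50.0, 0.54, 729.0, 1.91e-1, "S_mut8", UNIT_UM),
        "S_mut15": HillActivatorParams(50.0, 0.426, 2679.0, 4.45e-2, "S_mut15", UNIT_UM),
        "S_plux_rep": HillRepressorParams(0.252, 0.669, 735.0, 3.41e-1, "S_plux_rep", UNIT_UM),
        "R_mCh": HillActivatorParams(1103.0, 2.33, 2.16e4, 1.95e-2, "R_mCh", UNIT_MCHERRY),
    }


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def hill_fraction(x, K_d: float, n: float):
    """(x/K_d)^n / (1 + (x/K_d)^n), defined as exactly 0 at x = 0.

    Avoids the 0**n ambiguity for fractional n and overflow for large x by
    evaluating in terms of the ratio.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("input level must be non-negative")
    with np.errstate(over="ignore"):
        u = np.power(x / K_d, n)
    h = np.where(np.isinf(u), 1.0, u / (1.0 + u))
    h = np.where(x == 0, 0.0, h)
    return h if h.ndim else float(h)


def eval_activator(p: HillActivatorParams, x):
    """Evaluate the activator Hill curve at input level(s) x (same unit as K_d)."""
    h = hill_fraction(x, p.K_d, p.n)
    return p.beta_m * h + p.beta_m * p.beta_0


def eval_repressor(p: HillRepressorParams, x):
    """Evaluate the repressor Hill curve at input level(s) x."""
    h = hill_fraction(x, p.K_d, p.n)
    return p.alpha_hat_m * (h - p.alpha_0 - 1.0)


def eval_params(p: HillParams, x):
    """Evaluate either transfer-function family."""
    if isinstance(p, HillActivatorParams):
        return eval_activator(p, x)
    return eval_repressor(p, x)


# ---------------------------------------------------------------------------
# dose-response container
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    """A replicated dose-response table: input level vs median fluorescence.

    ``input_level`` carries the unit given in ``input_unit`` (uM inducer for
    sender/receiver characterizations, mCherry arb. units for the consortium
    activation function); ``response`` is median fluorescence in arb. units.
    """

    input_level: np.ndarray
    response: np.ndarray
    replicate: np.ndarray
    circuit_label: str = ""
    input_unit: str = UNIT_UM
    incubation_min: Optional[float] = None

    def __post_init__(self) -> None:
        self.input_level = np.asarray(self.input_level, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (len(self.input_level) == len(self.response) == len(self.replicate)):
            raise ValueError("input_level, response and replicate must have equal length")
        if np.any(self.input_level < 0):
            raise ValueError("input levels must be non-negative")

    @property
    def n_distinct_levels(self) -> int:
        return len(np.unique(self.input_level))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "input_level": self.input_level,
                "response": self.response,
                "replicate": self.replicate,
                "circuit_label": self.circuit_label,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, input_unit: str = UNIT_UM) -> "DoseResponse":
        df = pd.read_csv(path)
        required = {"input_level", "response", "replicate", "circuit_label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dose-response CSV {path} missing columns: {sorted(missing)}")
        if df.empty:
            raise ValueError(f"dose-response CSV {path} contains no rows")
        labels = df["circuit_label"].unique()
        label = str(labels[0]) if len(labels) == 1 else ""
        return cls(
            input_level=df["input_level"].to_numpy(float),
            response=df["response"].to_numpy(float),
            replicate=df["replicate"].to_numpy(),
            circuit_label=label,
            input_unit=input_unit,
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted parameters plus diagnostics.

    ``rms_log10_residual`` is the root-mean-square of log10(model/data); fits
    with a value above ``POOR_FIT_RMS_LOG10`` are flagged ``poor-fit`` and
    degenerate (flat) inputs are flagged ``flat-response`` without attempting
    a meaningful estimate of n.
    """

    params: HillParams
    residual_norm: float
    rms_log10_residual: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.converged and not self.flags


def _check_fittable(d: DoseResponse) -> None:
    if d.n_distinct_levels < MIN_DISTINCT_LEVELS:
        raise ValueError(
            f"need at least {MIN_DISTINCT_LEVELS} distinct input levels to fit a "
            f"Hill curve, got {d.n_distinct_levels}"
        )
    if np.any(d.response <= 0):
        raise ValueError("responses must be positive for log-space fitting")


def _flat(d: DoseResponse) -> bool:
    return float(d.response.max() / d.response.min()) < FLAT_RESPONSE_RATIO


def _fit_common(d, model_log10, theta0, lower, upper):
    """Least squares on log10-transformed responses (data span decades)."""
    y = np.log10(d.response)

    def resid(theta):
        return model_log10(theta) - y

    sol = least_squares(resid, theta0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return sol, rms


def _init_activator(d: DoseResponse) -> tuple[float, float, float, float]:
    rmax, rmin = float(d.response.max()), float(d.response.min())
    mid = 0.5 * (rmax + rmin)
    pos = d.input_level[d.input_level > 0]
    kd0 = float(pos[np.argmin(np.abs(d.response[d.input_level > 0] - mid))]) if len(pos) else 1.0
    return max(kd0, 1e-9), 1.0, rmax, max(rmin / rmax, 1e-6)


def fit_activator(d: DoseResponse, init: Optional[HillActivatorParams] = None) -> FitResult:
    """Fit the increasing Hill form to a dose-response table.

    Least squares on log10 responses; parameters bounded positive with
    n in (0.1, 10].  Returns a flagged (never silently wrong) :class:`FitResult`.
    """
    _check_fittable(d)
    flags: list[str] = []
    if _flat(d):
        flags.append("flat-response")
    if init is not None:
        theta0 = [init.K_d, init.n, init.beta_m, max(init.beta_0, 1e-6)]
    else:
        theta0 = list(_init_activator(d))

    x = d.input_level

    def model_log10(theta):
        kd, n, bm, b0 = theta
        return np.log10(bm * hill_fraction(x, kd, n) + bm * b0)

    lower = [1e-12, N_BOUNDS[0], 1e-12, 1e-9]
    upper = [np.inf, N_BOUNDS[1], np.inf, np.inf]
    theta0 = np.clip(theta0, lower, upper)
    sol, rms = _fit_common(d, model_log10, theta0, lower, upper)
    kd, n, bm, b0 = sol.x
    if rms > POOR_FIT_RMS_LOG10:
        flags.append("poor-fit")
    params = HillActivatorParams(kd, n, bm, b0, label=d.circuit_label, input_unit=d.input_unit)
    return FitResult(params, float(np.linalg.norm(sol.fun)), rms, bool(sol.success), flags, sol.message)


def fit_repressor(d: DoseResponse, init: Optional[HillRepressorParams] = None) -> FitResult:
    """Fit the decreasing Hill form (P_lux repressor) to a dose-response table."""
    _check_fittable(d)
    flags: list[str] = []
    if _flat(d):
        flags.append("flat-response")
    if init is not None:
        theta0 = [init.K_d, init.n, init.alpha_m, max(init.alpha_0, 1e-6)]
    else:
        rmax, rmin = float(d.response.max()), float(d.response.min())
        mid = 0.5 * (rmax + rmin)
        pos = d.input_level[d.input_level > 0]
        kd0 = float(pos[np.argmin(np.abs(d.response[d.input_level > 0] - mid))]) if len(pos) else 1.0
        theta0 = [max(kd0, 1e-9), 1.0, rmax, max(rmin / rmax, 1e-6)]

    x = d.input_level

    def model_log10(theta):
        kd, n, am, a0 = theta
        return np.log10(am / (1.0 + np.power(np.maximum(x, 0) / kd, n)) + a0 * am)

    lower = [1e-12, N_BOUNDS[0], 1e-12, 1e-9]
    upper = [np.inf, N_BOUNDS[1], np.inf, np.inf]
    theta0 = np.clip(theta0, lower, upper)
    sol, rms = _fit_common(d, model_log10, theta0, lower, upper)
    kd, n, am, a0 = sol.x
    if rms > POOR_FIT_RMS_LOG10:
        flags.append("poor-fit")
    params = HillRepressorParams(kd, n, am, a0, label=d.circuit_label, input_unit=d.input_unit)
    return FitResult(params, float(np.linalg.norm(sol.fun)), rms, bool(sol.success), flags, sol.message)


# ---------------------------------------------------------------------------
# synthetic dose-response generation (fixture generator)
# ---------------------------------------------------------------------------

def default_replicates(label: str) -> int:
    """Replicate count of the characterization assay for a registry row.

    Sender transfer functions were measured with ~10 independent replicates,
    receiver (OHC14 axis) curves with 3, and the consortium activation
    function (mCherry axis) from 12 measurement sets.
    """
    if label.startswith("S_"):
        return 10
    if label == "R_mCh":
        return 12
    return 3


def synth_dose_response(
    p: HillParams,
    n_levels: int = 8,
    n_replicates: Optional[int] = None,
    noise_cv: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    include_zero: bool = True,
) -> DoseResponse:
    """Generate a synthetic serial-dilution dose-response table from known params.

    Levels form a geometric series spanning K_d/27 .. 27*K_d (a 3-fold dilution
    ladder centred on the dissociation constant, mirroring the three-fold serial
    dilutions of the characterization assays), optionally plus a zero dose.
    ``n_replicates`` defaults to the assay's replication for the row's label
    (see :func:`default_replicates`).  ``noise_cv`` applies multiplicative
    Gaussian noise (seeded via ``rng``).
    """
    if n_replicates is None:
        n_replicates = default_replicates(p.label)
    levels = p.K_d * np.geomspace(1.0 / 27.0, 27.0, n_levels)
    if include_zero:
        levels = np.concatenate([[0.0], levels])
    x = np.tile(levels, n_replicates)
    rep = np.repeat(np.arange(1, n_replicates + 1), len(levels))
    y = np.asarray(eval_params(p, x), dtype=float)
    if noise_cv > 0:
        if rng is None:
            raise ValueError("noise_cv > 0 requires an rng")
        y = y * (1.0 + noise_cv * rng.standard_normal(len(y)))
        y = np.maximum(y, 1e-9)
    return DoseResponse(x, y, rep, circuit_label=p.label, input_unit=p.input_unit)


# ---------------------------------------------------------------------------
# registry persistence
# ---------------------------------------------------------------------------

def save_registry(registry: dict[str, HillParams], path) -> None:
    """Write a parameter registry as JSON."""
    out = {}
    for label, p in registry.items():
        if isinstance(p, HillActivatorParams):
            out[label] = {
                "model": "activator",
                "K_d": p.K_d,
                "n": p.n,
                "beta_m": p.beta_m,
                "beta_0": p.beta_0,
                "input_unit": p.input_unit,
            }
        else:
            out[label] = {
                "model": "repressor",
                "K_d": p.K_d,
                "n": p.n,
                "alpha_m": p.alpha_m,
                "alpha_0": p.alpha_0,
                "input_unit": p.input_unit,
            }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)


def load_registry(path) -> dict[str, HillParams]:
    """Read a parameter registry written by :func:`save_registry`."""
    with open(path) as fh:
        raw = json.load(fh)
    registry: dict[str, HillParams] = {}
    for label, rec in raw.items():
        unit = rec.get("input_unit", UNIT_UM)
        if rec["model"] == "activator":
            registry[label] = HillActivatorParams(
                rec["K_d"], rec["n"], rec["beta_m"], rec["beta_0"], label, unit
            )
        elif rec["model"] == "repressor":
            registry[label] = HillRepressorParams(
                rec["K_d"], rec["n"], rec["alpha_m"], rec["alpha_0"], label, unit
            )
        else:
            raise ValueError(f"unknown model kind {rec['model']!r} for {label!r}")
    return registry
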