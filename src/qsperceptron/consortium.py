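"""Forward model of the sender-receiver quorum-sensing consortium.

One sender group per input bit produces OHC14 in proportion to its promoter
strength (its perceptron weight, measured as mCherry at the induction dose);
the mixed senders' collective OHC14 is modelled as the weighted sum of the
pattern, expressed on the sender-mCherry axis.  The receiver's empirically
measured activation function sigma (EYFP vs sender mCherry) maps that sum to
the simulated readout.

A "0" input bit contributes nothing: experimentally those senders are
aTc-suppressed via a double-inversion circuit, which is abstracted here as
zero output (an optional "leaky" mode adds the basal activity instead).
Negative weights enter through the P_lux repressor promoter whose signed
weight is alpha_hat_m = -alpha_m; negative weighted sums are clamped to zero
before sigma since a signal concentration cannot be negative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .hill import (
    UNIT_MCHERRY,
    HillActivatorParams,
    HillRepressorParams,
    default_registry,
    eval_activator,
    hill_fraction,
)
from .patterns import Pattern, PatternSet

logger = logging.getLogger("qsperceptron")

__all__ = [
    "SenderSpec",
    "ReceiverSpec",
    "ConsortiumNetwork",
    "ResponseMatrix",
    "DEFAULT_INDUCTION_UM",
    "weighted_sum",
    "receiver_response",
    "receiver_response_derivative",
    "forward",
    "response_matrix",
    "count_unique_products",
    "network_from_weights",
]

#: OC6 concentration (uM) representing input bit "1" in the reference protocol
DEFAULT_INDUCTION_UM = 33.3


@dataclass
class SenderSpec:
    """One sender group: a signed weight realised by a P_lux promoter variant.

    ``weight_value`` is the sender output (mCherry arb. units) at the induction
    dose -- evaluated from the Hill parameters when not given, or overridden
    with a calibrated estimate.  ``sign`` is +1 for activator promoters and -1
    for the repressor (whose magnitude defaults to alpha_m, i.e. the signed
    weight alpha_hat_m = -alpha_m).
    """

    label: str = ""
    sign: int = 1
    params: Optional[Union[HillActivatorParams, HillRepressorParams]] = None
    induction_level: float = DEFAULT_INDUCTION_UM
    weight_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 (activator) or -1 (repressor)")
        if self.weight_value is None:
            if self.params is None:
                raise ValueError("need params or an explicit weight_value")
            if isinstance(self.params, HillRepressorParams):
                self.weight_value = self.params.alpha_m
                self.sign = -1
            else:
                self.weight_value = float(eval_activator(self.params, self.induction_level))
        if self.weight_value < 0:
            raise ValueError("weight_value is a magnitude; use sign=-1 for negative weights")

    @property
    def signed_weight(self) -> float:
        return self.sign * self.weight_value


@dataclass
class ReceiverSpec:
    """Receiver activation function sigma on the sender-mCherry axis."""

    params: HillActivatorParams = field(
        default_factory=lambda: default_registry()["R_mCh"]
    )
    label: str = "receiver"

    def __post_init__(self) -> None:
        if self.params.input_unit != UNIT_MCHERRY:
            raise ValueError(
                "receiver activation must be parameterized on the mCherry axis "
                f"(input_unit={UNIT_MCHERRY!r}), got {self.params.input_unit!r}"
            )

    @property
    def span(self) -> float:
        """Output dynamic range of sigma (beta_m)."""
        return self.params.span


@dataclass
class ConsortiumNetwork:
    """Ordered sender groups plus one receiver: the perceptron network.

    ``leaky`` switches the bit-0 policy from zero contribution (default,
    modelling aTc suppression) to adding each sender's basal activity.
    ``noise_cv`` enables multiplicative Gaussian weight noise, drawn from a
    generator seeded with ``seed``.
    """

    senders: list[SenderSpec]
    receiver: ReceiverSpec = field(default_factory=ReceiverSpec)
    leaky: bool = False
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def __len__(self) -> int:
        return len(self.senders)

    @property
    def weights(self) -> np.ndarray:
        """Signed weight vector (mCherry arb. units)."""
        return np.array([s.signed_weight for s in self.senders])

    def reset_rng(self) -> None:
        self._rng = np.random.default_rng(self.seed)


def _values(x) -> np.ndarray:
    v = x.values if isinstance(x, Pattern) else np.asarray(x, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("pattern entries must lie in [0, 1]")
    return v


def weighted_sum(net: ConsortiumNetwork, x, weights: Optional[np.ndarray] = None) -> float:
    """Collective OHC14 proxy: sum_i sign_i * weight_i * x_i (mCherry a.u.).

    Graded entries scale the calibrated weight linearly; a 0 bit contributes
    nothing unless the network is leaky, in which case the sender basal
    activity is added for activator senders with such parameters.
    """
    v = _values(x)
    w = net.weights if weights is None else weights
    if len(v) != len(w):
        raise ValueError(f"pattern length {len(v)} != sender count {len(w)}")
    s = float(w @ v)
    if net.leaky:
        for xi, spec in zip(v, net.senders):
            if xi == 0 and isinstance(spec.params, HillActivatorParams):
                s += spec.params.basal
    return s


def receiver_response(r: ReceiverSpec, s) -> float | np.ndarray:
    """sigma(s): simulated receiver EYFP for weighted sum(s) s.

    Negative sums are clamped to zero (signal concentrations cannot be
    negative); clamping is logged.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        logger.debug("clamping %d negative weighted sum(s) to 0", int(np.sum(s < 0)))
        s = np.maximum(s, 0.0)
    out = np.asarray(eval_activator(r.params, s))
    return out if out.ndim else float(out)


def receiver_response_derivative(r: ReceiverSpec, s) -> np.ndarray:
    """d sigma / d s, with the clamp's subgradient 0 for s <= 0."""
    p = r.params
    s = np.asarray(s, dtype=float)
    pos = s > 0
    d = np.zeros_like(s)
    if np.any(pos):
        h = hill_fraction(s[pos], p.K_d, p.n)
        # dh/ds = n * h * (1 - h) / s
        d[pos] = p.beta_m * p.n * h * (1.0 - h) / s[pos]
    return d


def forward(net: ConsortiumNetwork, x) -> float:
    """Pattern -> simulated receiver EYFP (arb. units).

    With weight noise enabled, each sender's weight magnitude is perturbed
    multiplicatively (CV = ``noise_cv``) before summation; draws advance the
    network's seeded generator.
    """
    w = net.weights
    if net.noise_cv > 0:
        w = w * (1.0 + net.noise_cv * net._rng.standard_normal(len(w)))
    s = weighted_sum(net, x, weights=w)
    return float(receiver_response(net.receiver, s))


@dataclass
class ResponseMatrix:
    """Simulated receiver EYFP for several weight vectors across a pattern set.

    Rows index weight vectors, columns patterns (in set order); ``sums`` holds
    the underlying weighted sums on the mCherry axis.
    """

    eyfp: np.ndarray
    sums: np.ndarray
    weight_labels: list[str]
    pattern_ids: list[str]

    def __post_init__(self) -> None:
        self.eyfp = np.atleast_2d(np.asarray(self.eyfp, dtype=float))
        self.sums = np.atleast_2d(np.asarray(self.sums, dtype=float))
        if self.eyfp.shape != self.sums.shape:
            raise ValueError("eyfp and sums must have the same shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.eyfp.shape

    def to_csv(self, path_eyfp, path_sums=None) -> None:
        pd.DataFrame(self.eyfp, index=self.weight_labels, columns=self.pattern_ids).to_csv(
            path_eyfp, index_label="weight_vector"
        )
        if path_sums is not None:
            pd.DataFrame(self.sums, index=self.weight_labels, columns=self.pattern_ids).to_csv(
                path_sums, index_label="weight_vector"
            )


def _pattern_id(p: Pattern, i: int) -> str:
    suffix = "clean" if p.is_clean else f"flip{p.noise_index}"
    return f"{i}_{p.category}_{suffix}"


def response_matrix(nets: Sequence[ConsortiumNetwork], s: PatternSet) -> ResponseMatrix:
    """Forward outputs of several networks (sharing a receiver) over a set."""
    n_patterns = len(s)
    sums = np.zeros((len(nets), n_patterns))
    eyfp = np.zeros_like(sums)
    for i, net in enumerate(nets):
        for j, p in enumerate(s):
            w = net.weights
            if net.noise_cv > 0:
                w = w * (1.0 + net.noise_cv * net._rng.standard_normal(len(w)))
            sums[i, j] = weighted_sum(net, p, weights=w)
            eyfp[i, j] = float(receiver_response(net.receiver, sums[i, j]))
    labels = [f"w{i}" for i in range(len(nets))]
    ids = [_pattern_id(p, j) for j, p in enumerate(s)]
    return ResponseMatrix(eyfp, sums, labels, ids)


def count_unique_products(
    m: ResponseMatrix | np.ndarray, tolerance: Optional[float] = None
) -> tuple[int, np.ndarray, np.ndarray]:
    """Distinct weighted-sum values across all entries, up to a tolerance.

    Many weight-pattern products coincide for symmetric letter sets; this
    counts the distinct values (default tolerance 1e-6 * max|sum|) and returns
    them with their multiplicities.
    """
    sums = m.sums if isinstance(m, ResponseMatrix) else np.asarray(m, dtype=float)
    if sums.size == 0:
        raise ValueError("empty product matrix")
    flat = np.sort(sums.ravel())
    if tolerance is None:
        tolerance = 1e-6 * float(np.max(np.abs(flat))) if np.any(flat != 0) else 0.0
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    values = [flat[0]]
    counts = [1]
    for v in flat[1:]:
        if v - values[-1] <= tolerance:
            counts[-1] += 1
        else:
            values.append(v)
            counts.append(1)
    return len(values), np.array(values), np.array(counts)


def network_from_weights(
    w: Sequence[float],
    receiver: Optional[ReceiverSpec] = None,
    leaky: bool = False,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> ConsortiumNetwork:
    """Network from a signed weight vector (calibrated mCherry levels)."""
    senders = [
        SenderSpec(label=f"s{i}", sign=(-1 if wi < 0 else 1), weight_value=abs(float(wi)))
        for i, wi in enumerate(w)
    ]
    return ConsortiumNetwork(
        senders, receiver or ReceiverSpec(), leaky=leaky, noise_cv=noise_cv, seed=seed
    )


# ---------------------------------------------------------------------------
# network config IO
# ---------------------------------------------------------------------------

def save_network(net: ConsortiumNetwork, path) -> None:
    payload = {
        "senders": [
            {
                "label": s.label,
                "sign": s.sign,
                "registry_ref": s.params.label if s.params is not None else None,
                "induction_level": s.induction_level,
                "weight_value": s.weight_value,
            }
            for s in net.senders
        ],
        "receiver": net.receiver.params.label or "R_mCh",
        "leaky": net.leaky,
        "noise_cv": net.noise_cv,
        "seed": net.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_network(path, registry=None) -> ConsortiumNetwork:
    registry = registry or default_registry()
    with open(path) as fh:
        payload = json.load(fh)
    senders = []
    for rec in payload["senders"]:
        params = registry.get(rec["registry_ref"]) if rec.get("registry_ref") else None
        senders.append(
            SenderSpec(
                label=rec.get("label", ""),
                sign=rec.get("sign", 1),
                params=params,
                induction_level=rec.get("induction_level", DEFAULT_INDUCTION_UM),
                weight_value=rec.get("weight_value"),
            )
        )
    receiver = ReceiverSpec(params=registry[payload.get("receiver", "R_mCh")])
    return ConsortiumNetwork(
        senders,
        receiver,
        leaky=payload.get("leaky", False),
        noise_cv=payload.get("noise_cv", 0.0),
        seed=payload.get("seed", 0),
    )
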