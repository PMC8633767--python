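"""Lesion-simulating variants of the SUSTAIN network.

Prefrontal damage is modelled by three manipulations of the intact network:

* **static attention** — the feature-tuning mechanism is lesioned by setting
  the attention focus ``r`` and the attention learning rate ``eta_lambda``
  to 0, so attention weights can never differentiate.
* **shuffled attention** — the attention-weight vector is randomly permuted
  before every trial; the network can still learn which dimension matters
  but cannot *maintain* attention on it across trials.
* **raised threshold** — the cluster recruitment threshold is raised above
  the control value, so fewer surprising events create new clusters.

A model variant is a declarative combination of these flags applied on top
of shared control parameters; the control model (all flags off) plus five
lesion variants form the comparison set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sustain import SustainParams

__all__ = [
    "ModelSpec",
    "CONTROL_SPEC",
    "make_model_table",
    "apply_static_attention",
    "shuffle_attention",
    "effective_params",
]


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration as flags over the three lesion manipulations."""

    model_id: int
    static_attention: bool = False
    shuffle_attention: bool = False
    raised_threshold: bool = False
    tau_lesion: float | None = None  # threshold used when raised_threshold is set

    def __post_init__(self):
        if self.raised_threshold and self.tau_lesion is not None:
            if not 0.0 <= self.tau_lesion <= 1.0:
                raise ValueError("tau_lesion must lie in [0, 1]")

    @property
    def n_extra_params(self) -> int:
        """Free parameters added on top of the control model."""
        return 1 if self.raised_threshold else 0

    def with_tau_lesion(self, tau_lesion: float) -> "ModelSpec":
        return replace(self, tau_lesion=tau_lesion)


CONTROL_SPEC = ModelSpec(model_id=0)


def make_model_table() -> list[ModelSpec]:
    """The control model plus the five lesion variants.

    Model 5 — shuffled attention combined with a raised recruitment
    threshold — is the configuration that a prefrontal lesion is expected to
    produce: attention that cannot be maintained on the relevant dimension,
    and sparser category representations.
    """
    return [
        ModelSpec(0),
        ModelSpec(1, static_attention=True),
        ModelSpec(2, shuffle_attention=True),
        ModelSpec(3, raised_threshold=True),
        ModelSpec(4, static_attention=True, raised_threshold=True),
        ModelSpec(5, shuffle_attention=True, raised_threshold=True),
    ]


def apply_static_attention(params: SustainParams) -> SustainParams:
    """Lesion the feature-tuning mechanism: r = 0 and eta_lambda = 0."""
    return params.replace(r=0.0, eta_lambda=0.0)


def shuffle_attention(lam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of the attention-weight vector.

    With two dimensions this swaps the weights with probability 1/2.  The
    permutation is not undone afterwards: weights live on in their shuffled
    slots, which breaks cross-trial alignment while leaving the multiset of
    values intact.
    """
    return np.asarray(lam)[rng.permutation(len(lam))]


def effective_params(params: SustainParams, spec: ModelSpec) -> SustainParams:
    """Resolve a ModelSpec against control parameters.

    Static attention zeroes ``r`` and ``eta_lambda``; a raised threshold
    replaces ``tau`` with ``tau_lesion`` (which must be set).  Shuffled
    attention is a per-trial operation and is handled by the simulation
    driver, not here.
    """
    p = params
    if spec.static_attention:
        p = apply_static_attention(p)
    if spec.raised_threshold:
        if spec.tau_lesion is None:
            raise ValueError("raised_threshold requires tau_lesion to be set")
        p = p.replace(tau=spec.tau_lesion)
    return p
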