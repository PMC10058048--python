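"""Connection-weight (Yoon) relative importance of the network inputs.

For a single-output network the signed relative importance of input i is

    RI_i % = ( sum_k w_ik w_kj ) / ( sum_i | sum_k w_ik w_kj | ) * 100

where w_ik is the weight from input i to hidden neuron k and w_kj the weight
from hidden neuron k to the output. The sums run over the hidden neurons and
the inputs respectively; biases carry no input index and are excluded. By
construction the absolute values sum to 100%.

Across an ensemble the per-factor mean and population SD of |RI| give the
bar-plus-error-bar summary of which extraction factor drives the yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann import EnsembleResult, NetworkWeights
from .dataset import FACTOR_COLUMNS

__all__ = ["ImportanceResult", "yoon_ri", "ensemble_ri"]


class DegenerateNetworkError(ValueError):
    """All input-hidden-output connection products are zero."""


@dataclass(frozen=True)
class ImportanceResult:
    """Per-member signed RI%% and the ensemble |RI|%% mean and SD per factor."""

    labels: tuple[str, ...]
    signed_ri: np.ndarray  # (n_members, n_inputs), percent, signed
    mean_abs_ri: np.ndarray  # (n_inputs,), percent
    sd_abs_ri: np.ndarray  # (n_inputs,), population SD, percent

    def ranking(self) -> tuple[str, ...]:
        """Factor labels from most to least influential by mean |RI|."""
        order = np.argsort(-self.mean_abs_ri)
        return tuple(self.labels[i] for i in order)


def yoon_ri(weights: NetworkWeights) -> np.ndarray:
    """Signed relative importance (percent) of each input of one network."""
    # numerator_i = sum_k w_ik * w_kj; biases excluded
    numer = weights.w_in.T @ weights.w_out  # (n_inputs,)
    denom = float(np.sum(np.abs(numer)))
    if denom == 0.0:
        raise DegenerateNetworkError(
            "all connection products are zero; RI undefined"
        )
    return numer / denom * 100.0


def ensemble_ri(
    ensemble: EnsembleResult, labels: tuple[str, ...] = FACTOR_COLUMNS
) -> ImportanceResult:
    """Mean and population SD of |RI| per factor across ensemble members.

    Magnitudes are aggregated (importance bars are conventionally positive);
    the per-member signed values are retained for direction-of-effect
    inspection.
    """
    signed = np.array([yoon_ri(m.weights) for m in ensemble.members])
    abs_ri = np.abs(signed)
    return ImportanceResult(
        labels=tuple(labels),
        signed_ri=signed,
        mean_abs_ri=abs_ri.mean(axis=0),
        sd_abs_ri=abs_ri.std(axis=0),  # population SD (ddof=0)
    )
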