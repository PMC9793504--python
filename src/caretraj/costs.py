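"""Substitution/indel cost model over the extended state alphabet.

Each channel's alphabet is extended with the three overlay states.  The
default ordinal scheme places the states on a line:

* level ``l`` at position ``l`` (0 = no utilization);
* DEAD one unit beyond the highest level, at position K — the minimal
  encoding of "furthest from no utilization" that keeps the matrix metric;
* INCAPACITATED at position K-1, i.e. cost-equivalent to the highest
  utilization level;

and sets ``s(a, b) = 2 * |pos(a) - pos(b)| / K``, so the maximum
substitution (DEAD vs none) is 2 on every channel and the half-max indel
rule gives ``indel = 1`` everywhere.  NONRESPONSE is equidistant: it costs
exactly the indel against every other state — the unique equidistant value
that preserves the triangle inequality against the DEAD/none pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DEAD, INCAP, NR, ChannelSpec

# Extended-alphabet row order: levels 0..K-1, then NR, INCAP, DEAD.
_OVERLAY_OFFSET = {NR: 0, INCAP: 1, DEAD: 2}


def ext_index(spec: ChannelSpec, code: int) -> int:
    """Map a cohort state code (level or negative overlay) to a matrix row."""
    if code >= 0:
        if code >= spec.k:
            raise ValueError(f"level {code} outside alphabet of {spec.name!r}")
        return code
    try:
        return spec.k + _OVERLAY_OFFSET[code]
    except KeyError:
        raise ValueError(f"unknown state code {code}") from None


def ext_size(spec: ChannelSpec) -> int:
    return spec.k + 3


@dataclass
class ChannelCosts:
    """Substitution matrix, indel cost and weight for one channel."""

    spec: ChannelSpec
    sub: np.ndarray  # (K+3, K+3), extended-alphabet order
    indel: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.sub = np.asarray(self.sub, dtype=float)
        m = ext_size(self.spec)
        if self.sub.shape != (m, m):
            raise ValueError(
                f"channel {self.spec.name!r}: substitution matrix must be "
                f"{m}x{m} (levels + NR/INCAP/DEAD)"
            )
        if not np.allclose(self.sub, self.sub.T):
            raise ValueError(f"channel {self.spec.name!r}: matrix not symmetric")
        if np.any(np.diag(self.sub) != 0):
            raise ValueError(f"channel {self.spec.name!r}: diagonal must be zero")
        if np.any(self.sub < 0):
            raise ValueError(f"channel {self.spec.name!r}: negative cost")


@dataclass
class CostModel:
    """Per-channel costs plus the pooled indel used by the multichannel DP."""

    channels: list[ChannelCosts]

    @property
    def specs(self) -> list[ChannelSpec]:
        return [c.spec for c in self.channels]

    @property
    def pooled_indel(self) -> float:
        return float(sum(c.weight * c.indel for c in self.channels))

    def pooled_sub(self, x: np.ndarray, y: np.ndarray) -> float:
        """Pooled substitution cost between two multichannel states.

        ``x`` and ``y`` are vectors of cohort state codes, one per channel.
        """
        total = 0.0
        for j, ch in enumerate(self.channels):
            total += ch.weight * ch.sub[
                ext_index(ch.spec, int(x[j])), ext_index(ch.spec, int(y[j]))
            ]
        return total


def _ordinal_matrix(spec: ChannelSpec) -> np.ndarray:
    k = spec.k
    # Positions on the line; NR handled separately.
    pos = np.empty(k + 3)
    pos[:k] = np.arange(k)
    pos[ext_index(spec, INCAP)] = k - 1
    pos[ext_index(spec, DEAD)] = k
    sub = 2.0 * np.abs(pos[:, None] - pos[None, :]) / k
    i_nr = ext_index(spec, NR)
    indel = sub.max() / 2.0  # half-max rule; equals 1 under this scheme
    sub[i_nr, :] = indel
    sub[:, i_nr] = indel
    sub[i_nr, i_nr] = 0.0
    return sub


def build_cost_model(
    specs: list[ChannelSpec],
    weights: dict[str, float] | None = None,
    overrides: dict[str, np.ndarray] | None = None,
) -> CostModel:
    """Build the default ordinal cost model, optionally overriding channels.

    ``overrides`` maps a channel name to a full extended-alphabet
    substitution matrix; the half-max indel rule is re-applied to it.
    ``weights`` maps channel names to channel weights (default 1).
    """
    weights = weights or {}
    overrides = overrides or {}
    channels = []
    for spec in specs:
        sub = overrides.get(spec.name)
        sub = _ordinal_matrix(spec) if sub is None else np.asarray(sub, dtype=float)
        channels.append(
            ChannelCosts(
                spec=spec,
                sub=sub,
                indel=float(sub.max()) / 2.0,
                weight=float(weights.get(spec.name, 1.0)),
            )
        )
    return CostModel(channels)
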