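"""Domain types for multichannel annual state sequences.

A cohort records, for each individual and each annual wave, one categorical
state per health-service channel (ambulatory care, emergency care,
hospitalization, professional home care, nursing home).  Each channel has an
ordinal alphabet whose position 0 means "no utilization".  Three overlay
states — random nonresponse, incapacitated (too unwell to participate) and
dead — apply to all channels of a person-wave at once; death is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Number of annual waves in the study design.
N_WAVES = 11

# Overlay states are encoded as negative integers so that any nonnegative
# value is an ordinal channel level.
NR = -1
INCAP = -2
DEAD = -3

OVERLAY_CODES = {NR: "NR", INCAP: "INCAP", DEAD: "DEAD"}
OVERLAY_LABELS = {v: k for k, v in OVERLAY_CODES.items()}


class ValidationError(ValueError):
    """A cohort or table violates a structural invariant."""


@dataclass(frozen=True)
class ChannelSpec:
    """Ordinal alphabet of one health-service channel.

    Parameters
    ----------
    name:
        Full channel name (e.g. ``"ambulatory"``).
    code:
        Short column name used in wide-format files (e.g. ``"amb"``).
    levels:
        Utilization-state labels ordered from position 0 ("no utilization")
        to position K-1 (highest utilization).
    """

    name: str
    code: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValidationError(f"channel {self.name!r}: need K >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError(f"channel {self.name!r}: duplicate level labels")
        if "none" not in self.levels[0]:
            raise ValidationError(
                f"channel {self.name!r}: position 0 must denote no utilization"
            )
        for lab in self.levels:
            if lab in OVERLAY_LABELS:
                raise ValidationError(
                    f"channel {self.name!r}: level {lab!r} clashes with an overlay code"
                )

    @property
    def k(self) -> int:
        """Number of ordinal levels."""
        return len(self.levels)

    def encode(self, label: str) -> int:
        """Map a state label (level or overlay) to its integer code."""
        if label in OVERLAY_LABELS:
            return OVERLAY_LABELS[label]
        try:
            return self.levels.index(label)
        except ValueError:
            raise ValidationError(
                f"unknown state {label!r} for channel {self.name!r}"
            ) from None

    def decode(self, code: int) -> str:
        if code < 0:
            return OVERLAY_CODES[code]
        return self.levels[code]


def default_channel_specs() -> list[ChannelSpec]:
    """The five default channels and their ordinal alphabets.

    Ambulatory care (physician appointments) uses four frequency bands; the
    other channels use three.  Home care distinguishes temporary from regular
    provision, nursing home temporary stays from permanent residence.  The
    count-to-category cutoffs behind the band labels are configurable — they
    are questionnaire-specific and carry no meaning inside the pipeline,
    which only uses ordinal positions.
    """
    return [
        ChannelSpec("ambulatory", "amb", ("none", "low", "medium", "high")),
        ChannelSpec("emergency", "emerg", ("none", "one", "multiple")),
        ChannelSpec("hospitalization", "hosp", ("none", "one", "multiple")),
        ChannelSpec("home_care", "homecare", ("none", "temporary", "regular")),
        ChannelSpec("nursing_home", "nursinghome", ("none", "temporary", "permanent")),
    ]


@dataclass
class CovariateTable:
    """Baseline covariates, one row per individual.

    ``categorical`` maps covariate name -> declared category list; values
    outside the list (other than missing, i.e. NaN/empty) are rejected.
    ``numeric`` lists numeric covariates such as age in years.
    """

    data: pd.DataFrame  # indexed by individual id
    categorical: dict[str, list[str]] = field(default_factory=dict)
    numeric: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, cats in self.categorical.items():
            if name not in self.data.columns:
                raise ValidationError(f"covariate {name!r} missing from table")
            col = self.data[name]
            bad = col.dropna()[~col.dropna().isin(cats)]
            if len(bad):
                raise ValidationError(
                    f"covariate {name!r}: values outside declared categories: "
                    f"{sorted(bad.unique())}"
                )
        for name in self.numeric:
            if name not in self.data.columns:
                raise ValidationError(f"covariate {name!r} missing from table")

    def subset(self, ids) -> "CovariateTable":
        return CovariateTable(
            self.data.loc[list(ids)], dict(self.categorical), list(self.numeric)
        )


@dataclass
class Cohort:
    """Per-individual, per-wave multichannel state matrix.

    ``states`` has shape (n_individuals, n_waves, n_channels) with ordinal
    levels as nonnegative integers and overlays as negative codes.  Waves are
    1-based in all user-facing I/O (years since entry).
    """

    ids: list
    specs: list[ChannelSpec]
    states: np.ndarray
    covariates: CovariateTable | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_waves(self) -> int:
        return self.states.shape[1]

    @property
    def n_channels(self) -> int:
        return self.states.shape[2]

    def validate(self) -> None:
        n, t, c = self.states.shape
        if len(self.ids) != n:
            raise ValidationError("ids length does not match state matrix")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate individual ids")
        if c != len(self.specs):
            raise ValidationError("channel count does not match specs")
        for j, spec in enumerate(self.specs):
            col = self.states[:, :, j]
            if col.max(initial=-3) >= spec.k or col.min(initial=0) < DEAD:
                i, w = np.argwhere((col >= spec.k) | (col < DEAD))[0]
                raise ValidationError(
                    f"individual {self.ids[i]!r} wave {w + 1}: state code "
                    f"{col[i, w]} outside alphabet of channel {spec.name!r}"
                )
        overlay = self.states < 0
        mixed = overlay.any(axis=2) & ~overlay.all(axis=2)
        if mixed.any():
            i, w = np.argwhere(mixed)[0]
            raise ValidationError(
                f"individual {self.ids[i]!r} wave {w + 1}: overlay state must "
                "cover all channels"
            )
        same = (self.states == self.states[:, :, :1]).all(axis=2)
        bad = overlay.all(axis=2) & ~same
        if bad.any():
            i, w = np.argwhere(bad)[0]
            raise ValidationError(
                f"individual {self.ids[i]!r} wave {w + 1}: channels carry "
                "different overlay states"
            )
        dead = self.states[:, :, 0] == DEAD
        resurrect = dead[:, :-1] & ~dead[:, 1:]
        if resurrect.any():
            i, w = np.argwhere(resurrect)[0]
            raise ValidationError(
                f"individual {self.ids[i]!r}: DEAD at wave {w + 1} but not at "
                f"wave {w + 2} (death is absorbing)"
            )
        if self.covariates is not None:
            missing = set(self.ids) - set(self.covariates.data.index)
            if missing:
                raise ValidationError(f"covariates missing for ids {sorted(missing)!r}")

    def known_mask(self) -> np.ndarray:
        """(n, waves) bool: wave state is known (level, INCAP or DEAD).

        Nonresponse is the only unknown state: confirmed death and confirmed
        incapacity are observations about the individual, whereas a
        nonresponse carries no information.
        """
        return self.states[:, :, 0] != NR

    def subset(self, indices) -> "Cohort":
        indices = np.asarray(indices)
        ids = [self.ids[i] for i in indices]
        cov = self.covariates.subset(ids) if self.covariates is not None else None
        return Cohort(ids, self.specs, self.states[indices], cov)


def filter_min_observations(
    cohort: Cohort, min_obs: int = 6
) -> tuple[Cohort, list, list]:
    """Apply the study-inclusion rule: at least ``min_obs`` known waves.

    A wave counts as observed when its state is a utilization level,
    INCAPACITATED or DEAD; nonresponse waves do not count.  Returns the
    retained sub-cohort plus the retained and excluded id lists.
    """
    if not 1 <= min_obs <= cohort.n_waves:
        raise ValueError(f"min_obs must be in 1..{cohort.n_waves}")
    known = cohort.known_mask().sum(axis=1)
    keep = np.flatnonzero(known >= min_obs)
    drop = np.flatnonzero(known < min_obs)
    retained = [cohort.ids[i] for i in keep]
    excluded = [cohort.ids[i] for i in drop]
    return cohort.subset(keep), retained, excluded
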