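"""CSV input/output for cohorts and covariate tables.

Two trajectory dialects are supported:

* long — columns ``id, wave, channel, state``, one row per cell;
* wide — columns ``id, wave`` plus one short-named column per channel.

State codes are channel-level labels or the overlay codes ``NR`` / ``INCAP``
/ ``DEAD``.  Waves are 1-based.  Files are UTF-8 with a header row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    NR,
    ChannelSpec,
    Cohort,
    CovariateTable,
    ValidationError,
)


class ParseError(ValueError):
    """A trajectory or covariate file is malformed."""


def _encode_cell(spec: ChannelSpec, label, path, line) -> int:
    try:
        return spec.encode(str(label))
    except ValidationError as exc:
        raise ParseError(f"{path}, line {line}: {exc}") from None


def read_trajectories(path, specs: list[ChannelSpec]) -> tuple[list, np.ndarray]:
    """Read a long- or wide-format trajectory CSV (dialect auto-detected)."""
    df = pd.read_csv(path, dtype=str)
    cols = set(df.columns)
    if {"id", "wave", "channel", "state"} <= cols:
        return _from_long(df, specs, path)
    if {"id", "wave"} <= cols and {s.code for s in specs} <= cols:
        return _from_wide(df, specs, path)
    raise ParseError(
        f"{path}: columns {sorted(cols)} match neither the long dialect "
        "(id, wave, channel, state) nor the wide dialect (id, wave, "
        + ", ".join(s.code for s in specs)
        + ")"
    )


def _parse_wave(value, n_waves, path, line) -> int:
    try:
        wave = int(value)
    except (TypeError, ValueError):
        raise ParseError(f"{path}, line {line}: wave {value!r} is not an integer")
    if not 1 <= wave <= n_waves:
        raise ParseError(f"{path}, line {line}: wave {wave} outside 1..{n_waves}")
    return wave


def _from_long(df, specs, path):
    from .model import N_WAVES

    by_name = {s.name: (j, s) for j, s in enumerate(specs)}
    ids = list(dict.fromkeys(df["id"]))
    idx = {v: i for i, v in enumerate(ids)}
    states = np.full((len(ids), N_WAVES, len(specs)), NR, dtype=np.int8)
    filled = np.zeros(states.shape, dtype=bool)
    for line, row in enumerate(df.itertuples(index=False), start=2):
        if row.channel not in by_name:
            raise ParseError(f"{path}, line {line}: unknown channel {row.channel!r}")
        j, spec = by_name[row.channel]
        wave = _parse_wave(row.wave, N_WAVES, path, line)
        i = idx[row.id]
        states[i, wave - 1, j] = _encode_cell(spec, row.state, path, line)
        filled[i, wave - 1, j] = True
    if not filled.all():
        i, w, j = np.argwhere(~filled)[0]
        raise ParseError(
            f"{path}: missing cell for id {ids[i]!r}, wave {w + 1}, "
            f"channel {specs[j].name!r} (use NR for nonresponse)"
        )
    return ids, states


def _from_wide(df, specs, path):
    from .model import N_WAVES

    ids = list(dict.fromkeys(df["id"]))
    idx = {v: i for i, v in enumerate(ids)}
    states = np.full((len(ids), N_WAVES, len(specs)), NR, dtype=np.int8)
    filled = np.zeros((len(ids), N_WAVES), dtype=bool)
    for line, row in enumerate(df.itertuples(index=False), start=2):
        wave = _parse_wave(row.wave, N_WAVES, path, line)
        i = idx[row.id]
        for j, spec in enumerate(specs):
            states[i, wave - 1, j] = _encode_cell(
                spec, getattr(row, spec.code), path, line
            )
        filled[i, wave - 1] = True
    if not filled.all():
        i, w = np.argwhere(~filled)[0]
        raise ParseError(f"{path}: missing row for id {ids[i]!r}, wave {w + 1}")
    return ids, states


def read_covariates(
    path,
    categorical: dict[str, list[str]] | None = None,
    numeric: list[str] | None = None,
) -> CovariateTable:
    """Read a covariate CSV (column ``id`` + one column per covariate).

    Empty cells are missing.  Columns not declared categorical or numeric are
    treated as categorical with categories inferred from the observed values.
    """
    df = pd.read_csv(path, dtype=str).set_index("id")
    categorical = dict(categorical or {})
    numeric = list(numeric or [])
    for col in numeric:
        df[col] = pd.to_numeric(df[col])
    for col in df.columns:
        if col not in numeric and col not in categorical:
            categorical[col] = sorted(df[col].dropna().unique())
    return CovariateTable(df, categorical, numeric)


def read_cohort(
    trajectory_path,
    covariate_path=None,
    specs: list[ChannelSpec] | None = None,
    **covariate_kwargs,
) -> Cohort:
    """Read and validate a cohort from trajectory (+ optional covariate) CSVs."""
    from .model import default_channel_specs

    specs = specs or default_channel_specs()
    ids, states = read_trajectories(trajectory_path, specs)
    cov = read_covariates(covariate_path, **covariate_kwargs) if covariate_path else None
    return Cohort(ids, specs, states, cov)


def write_trajectories(cohort: Cohort, path, dialect: str = "long") -> None:
    """Write the trajectory matrix to CSV in the requested dialect."""
    rows = []
    if dialect == "long":
        for i, ind in enumerate(cohort.ids):
            for w in range(cohort.n_waves):
                for j, spec in enumerate(cohort.specs):
                    rows.append(
                        (ind, w + 1, spec.name, spec.decode(cohort.states[i, w, j]))
                    )
        pd.DataFrame(rows, columns=["id", "wave", "channel", "state"]).to_csv(
            path, index=False
        )
    elif dialect == "wide":
        for i, ind in enumerate(cohort.ids):
            for w in range(cohort.n_waves):
                rows.append(
                    (ind, w + 1)
                    + tuple(
                        spec.decode(cohort.states[i, w, j])
                        for j, spec in enumerate(cohort.specs)
                    )
                )
        cols = ["id", "wave"] + [s.code for s in cohort.specs]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_covariates(table: CovariateTable, path) -> None:
    table.data.to_csv(path, index=True, index_label="id")
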