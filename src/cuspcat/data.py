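"""Study-table ingestion and screening.

A :class:`StudyTable` holds one numeric column per model role — the state
(outcome), the asymmetry predictor and the bifurcation predictor — after
listwise deletion: any row with a missing or non-numeric value in a role
column is dropped and logged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

ROLES = ("state", "asymmetry", "bifurcation")

#: default column-name mapping used by the pipeline and the generator
DEFAULT_ROLES = {"state": "engagement", "asymmetry": "liking", "bifurcation": "disorder"}


@dataclass
class StudyTable:
    """Role-tagged numeric data after listwise deletion."""

    data: pd.DataFrame
    roles: dict[str, str]
    n_raw: int
    deletion_log: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_analyzed(self) -> int:
        return len(self.data)

    @property
    def state(self) -> np.ndarray:
        return self.data[self.roles["state"]].to_numpy(dtype=float)

    @property
    def asymmetry(self) -> np.ndarray:
        return self.data[self.roles["asymmetry"]].to_numpy(dtype=float)

    @property
    def bifurcation(self) -> np.ndarray:
        return self.data[self.roles["bifurcation"]].to_numpy(dtype=float)

    def constant_roles(self) -> list[str]:
        """Role columns with zero variance (warned here, fatal at fit time)."""
        out = []
        for role in ROLES:
            col = self.data[self.roles[role]].to_numpy(dtype=float)
            if len(col) > 0 and np.ptp(col) == 0.0:
                out.append(role)
        return out

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, roles: dict[str, str] | None = None) -> "StudyTable":
        """Screen a raw dataframe: coerce role columns to numeric, drop
        incomplete rows (listwise deletion), keep a log of dropped indices."""
        roles = dict(roles or DEFAULT_ROLES)
        missing = [r for r in ROLES if r not in roles]
        if missing:
            raise SchemaError(f"role map lacks required roles: {missing}")
        absent = [c for c in (roles[r] for r in ROLES) if c not in df.columns]
        if absent:
            raise SchemaError(f"input table lacks role column(s): {absent}")
        out = df.copy()
        for role in ROLES:
            col = pd.to_numeric(out[roles[role]], errors="coerce")
            out[roles[role]] = col.where(np.isfinite(col))
        keep = out[[roles[r] for r in ROLES]].notna().all(axis=1)
        dropped = tuple(int(i) for i in np.flatnonzero(~keep.to_numpy()))
        out = out.loc[keep].reset_index(drop=True)
        if len(out) == 0:
            raise SchemaError("no complete rows remain after listwise deletion")
        table = cls(data=out, roles=roles, n_raw=len(df), deletion_log=dropped)
        const = table.constant_roles()
        if const:
            warnings.warn(
                f"constant role column(s) {const}: the model will not be identifiable",
                UserWarning,
                stacklevel=2,
            )
        return table

    @classmethod
    def from_arrays(cls, state, asymmetry, bifurcation, roles=None) -> "StudyTable":
        roles = dict(roles or DEFAULT_ROLES)
        df = pd.DataFrame(
            {
                roles["state"]: np.asarray(state, dtype=float),
                roles["asymmetry"]: np.asarray(asymmetry, dtype=float),
                roles["bifurcation"]: np.asarray(bifurcation, dtype=float),
            }
        )
        return cls.from_dataframe(df, roles)


def read_table(path, roles: dict[str, str] | None = None, delimiter: str | None = None) -> StudyTable:
    """Read a delimited text file (CSV/TSV; delimiter sniffed when not given)
    and screen it into a :class:`StudyTable`.

    Empty strings, ``NA`` tokens and non-parseable values count as missing;
    parsing is locale-independent (decimal point).
    """
    try:
        if delimiter is None:
            df = pd.read_csv(path, sep=None, engine="python")
        else:
            df = pd.read_csv(path, sep=delimiter)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"could not parse {path!r}: {exc}") from exc
    return StudyTable.from_dataframe(df, roles)
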