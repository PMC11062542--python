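"""Reading numeric input and serialising fit reports."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .select import FitResult

__all__ = ["read_numeric", "FitReport"]


def read_numeric(path, column: str | int | None = None) -> np.ndarray:
    """Read a numeric vector from a text file.

    With ``column=None`` the file must hold one value per line (blank
    lines skipped); otherwise it is parsed as CSV and ``column`` selects a
    column by header name or 0-based integer index.  Decimal points are
    always ``.`` regardless of locale.
    """
    if column is None:
        values = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                token = line.strip()
                if not token:
                    continue
                try:
                    values.append(float(token))
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: cannot parse {token!r} as a number"
                    ) from None
        data = np.asarray(values, dtype=float)
    else:
        frame = pd.read_csv(path)
        if isinstance(column, int) or (isinstance(column, str) and column.isdigit()):
            idx = int(column)
            if not 0 <= idx < frame.shape[1]:
                raise ValueError(f"{path}: column index {idx} out of range")
            series = frame.iloc[:, idx]
        else:
            if column not in frame.columns:
                raise ValueError(
                    f"{path}: no column {column!r}; available: {list(frame.columns)}"
                )
            series = frame[column]
        series = series.dropna()
        try:
            data = series.astype(float).to_numpy()
        except ValueError as exc:
            raise ValueError(f"{path}: column {column!r} is not numeric: {exc}") from None
    if data.size == 0:
        raise ValueError(f"{path}: no numeric values found")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite values in input")
    return data


@dataclass(frozen=True)
class FitReport:
    """JSON-serialisable summary of one fitted irregular histogram."""

    n: int
    min: float
    max: float
    k: int
    h: float
    K: int
    final_aic: float
    breaks: tuple[float, ...]
    group_counts: tuple[int, ...]
    heights: tuple[float, ...]
    cut_indices: tuple[int, ...]
    trace: tuple[dict, ...]

    @classmethod
    def from_fit(cls, fit: FitResult) -> "FitReport":
        grid, hist = fit.fine_grid, fit.histogram
        return cls(
            n=grid.n,
            min=float(grid.breaks[0]),
            max=float(grid.breaks[-1]),
            k=grid.k,
            h=grid.h,
            K=hist.K,
            final_aic=float(fit.trace.final_aic),
            breaks=tuple(float(b) for b in hist.breaks),
            group_counts=tuple(int(c) for c in hist.group_counts),
            heights=tuple(float(v) for v in hist.heights),
            cut_indices=fit.cuts.cut_indices,
            trace=tuple(
                {
                    "K": s.K,
                    "cut_index": s.cut_index,
                    "aic": s.aic,
                    "accepted": s.accepted,
                }
                for s in fit.trace.steps
            ),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FitReport":
        raw = json.loads(text)
        for key in ("breaks", "group_counts", "heights", "cut_indices"):
            raw[key] = tuple(raw[key])
        raw["trace"] = tuple(raw["trace"])
        return cls(**raw)

    def breaks_table(self) -> pd.DataFrame:
        """Per-bin table: left/right break, count, density height."""
        return pd.DataFrame(
            {
                "break_left": self.breaks[:-1],
                "break_right": self.breaks[1:],
                "count": self.group_counts,
                "height": self.heights,
            }
        )
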