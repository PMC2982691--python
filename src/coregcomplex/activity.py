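"""Condition-specific transcription-factor activity.

A TF counts as active in a condition when it reaches a sufficiently high
expression level there.  Two routes are provided:

* :func:`determine_active_tfs` -- a transparent quantile-threshold call: a
  TF is active in a condition iff its mean expression over observed time
  points is at or above the ``level_quantile`` quantile of all gene means
  in that condition (default 0.75, per condition);
* :func:`load_activity_table` -- ingest externally computed per-condition
  activity labels (e.g. from an upstream activity caller), the recommended
  route when such labels exist.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .data import ExpressionPanel, TFActivityTable
from .io import _open_text

logger = logging.getLogger(__name__)

__all__ = ["determine_active_tfs", "load_activity_table"]

_TRUE = {"T", "TRUE", "1", "Y", "YES"}
_FALSE = {"F", "FALSE", "0", "N", "NO"}


def determine_active_tfs(
    panel: ExpressionPanel,
    tfs: Iterable[str],
    level_quantile: float = 0.75,
) -> TFActivityTable:
    """Call per-condition TF activity by an expression-level quantile.

    The per-gene summary is the mean over non-missing time points.  The
    threshold is the ``level_quantile`` quantile of all gene summaries in
    that condition; ties at the boundary are active (``>=``).  TFs absent
    from a condition's expression data are inactive there.
    """
    if not (0.0 < level_quantile < 1.0):
        raise ValueError(f"level_quantile must be in (0, 1), got {level_quantile}")
    tfs = frozenset(tfs)
    flags: dict[tuple[str, str], bool] = {}
    for cond in panel.conditions:
        df = panel.frame(cond)
        with np.errstate(invalid="ignore"):
            summaries = np.nanmean(df.to_numpy(), axis=1)
        observed = summaries[np.isfinite(summaries)]
        threshold = float(np.quantile(observed, level_quantile))
        by_gene = dict(zip(df.index, summaries))
        for tf in tfs:
            s = by_gene.get(tf, np.nan)
            flags[(tf, cond)] = bool(np.isfinite(s) and s >= threshold)
    return TFActivityTable(
        tfs=tfs, conditions=tuple(panel.conditions), flags=flags
    )


def load_activity_table(
    path: str | Path, tfs: Iterable[str], conditions: Sequence[str]
) -> TFActivityTable:
    """Load a three-column TSV ``tf<TAB>condition<TAB>{T,F}``.

    Pairs absent from the file default to inactive (warning logged);
    unknown condition labels are an error.
    """
    conditions = tuple(conditions)
    known = set(conditions)
    flags: dict[tuple[str, str], bool] = {}
    with _open_text(path) as fh:
        for line_no, ln in enumerate(fh, start=1):
            if ln.strip() == "":
                continue
            cells = ln.rstrip("\n").split("\t")
            if len(cells) < 3:
                raise ValueError(f"{path}: malformed activity row at line {line_no}")
            tf, cond, flag = (c.strip() for c in cells[:3])
            if cond not in known:
                raise ValueError(
                    f"{path}: unknown condition label {cond!r} at line {line_no}"
                )
            up = flag.upper()
            if up in _TRUE:
                flags[(tf, cond)] = True
            elif up in _FALSE:
                flags[(tf, cond)] = False
            else:
                raise ValueError(
                    f"{path}: unrecognised activity flag {flag!r} at line {line_no}"
                )
    return TFActivityTable.from_partial(tfs, conditions, flags, warn_missing=True)
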