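"""Exposure metameters: the raw variable of interest and its logarithm.

Each metabolite is modelled once per metameter so that both a linear and a
log-shaped dependence on the exposure (e.g. age) can be detected; with the
default pair this yields 2 models per metabolite and 2*p models in the joint
family.  No centering or scaling is applied: effects are reported per raw
unit of the chosen metameter.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

ARITHMETIC = "arithmetic"
LOGARITHMIC = "logarithmic"


@dataclass(frozen=True)
class MetameterSet:
    """Named, column-aligned transformed versions of one exposure variable."""

    names: Tuple[str, ...]
    columns: np.ndarray  # n x m
    source_name: str

    def __post_init__(self) -> None:
        if self.columns.ndim != 2 or self.columns.shape[1] != len(self.names):
            raise ValueError("columns must be an n x m matrix matching names")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("metameter columns must be finite")

    @property
    def m(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        try:
            return self.columns[:, self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown metameter {name!r}; available: {list(self.names)}")


def make_metameters(
    x: Sequence[float],
    include_log: bool = True,
    source_name: str = "x",
    log_base: Optional[float] = None,
    sample_ids: Optional[Sequence] = None,
) -> MetameterSet:
    """Build the arithmetic (identity) and logarithmic metameter columns.

    The logarithm is natural by default (``log_base`` switches, e.g., to 2 for
    cross-study comparability).  Requires strictly positive exposures when the
    logarithmic metameter is included; offending samples are named in the
    error.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{source_name}: exposure contains non-finite values")
    if not include_log:
        return MetameterSet((ARITHMETIC,), x[:, None].copy(), source_name)
    bad = np.flatnonzero(x <= 0)
    if bad.size:
        ids = [sample_ids[i] for i in bad] if sample_ids is not None else bad.tolist()
        shown = ids[:10]
        raise ValueError(
            f"{source_name}: logarithmic metameter needs positive values; "
            f"non-positive at samples {shown}{'...' if len(ids) > 10 else ''}"
        )
    logx = np.log(x) if log_base is None else np.log(x) / np.log(log_base)
    return MetameterSet((ARITHMETIC, LOGARITHMIC), np.column_stack([x, logx]), source_name)
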