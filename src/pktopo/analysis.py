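"""Topological-constraint fractions, summary tables, and size landscapes.

The constraint fraction F_x = N_x / N_tot measures how strongly the motif
topology restricts helix configurations: N_x is the number of allowed
configurations with loop subset x connected, N_tot the total enumerated (or
sampled) configurations.  Smaller F means a stronger constraint.  Fractions
are reported in two-significant-figure scientific notation ("4.3E-3");
averages are always taken over the unrounded values and rounded only at
rendering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig, REDUCED_PROFILE
from .motifs import MotifSpec
from .sampler import ViabilityCounts, count_pk

__all__ = [
    "ConstraintFraction",
    "LandscapeGrid",
    "fraction",
    "sci2",
    "mantissa_exponent",
    "summarize_cases",
    "group_average",
    "landscape",
    "PK_COLUMNS",
    "KISS_COLUMNS",
]

#: summary-table column -> loop-subset label
PK_COLUMNS = {"F_2": "2", "F_12": "12", "F_23": "23", "F_PK": "123"}
KISS_COLUMNS = {"F_24": "24", "F_124": "124", "F_234": "234",
                "F_245": "245", "F_246": "246", "F_KISS": "123456"}


def mantissa_exponent(value: float) -> tuple[float, int]:
    """Decompose ``value`` as a * 10**b with a in [1, 10); 0 -> (0, 0)."""
    if value == 0:
        return 0.0, 0
    b = int(math.floor(math.log10(abs(value))))
    a = value / 10.0 ** b
    # guard against log10 edge rounding
    if abs(a) >= 10.0:
        a, b = a / 10.0, b + 1
    elif abs(a) < 1.0:
        a, b = a * 10.0, b - 1
    return a, b


def sci2(value: float) -> str:
    """Two-significant-figure scientific notation, ASCII ("4.3E-3").

    Rounding is half-away-from-zero on the mantissa; a mantissa that rounds
    to 10 carries into the exponent.
    """
    value = float(value)
    if value == 0:
        return "0"
    a, b = mantissa_exponent(value)
    a = float(Decimal(repr(float(a))).quantize(Decimal("0.1"),
                                               rounding=ROUND_HALF_UP))
    if abs(a) >= 10.0:
        a, b = a / 10.0, b + 1
    return f"{a:.1f}E{b}"


@dataclass(frozen=True)
class ConstraintFraction:
    """An allowed-configuration fraction F_x = N_x / N_tot."""

    label: str
    n_allowed: int
    n_total: int
    value: float = field(init=False)
    mantissa_a: float = field(init=False)
    exponent_b: int = field(init=False)

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_allowed <= self.n_total:
            raise ValueError(
                f"n_allowed={self.n_allowed} outside [0, {self.n_total}]")
        value = self.n_allowed / self.n_total
        a, b = mantissa_exponent(value)
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "mantissa_a", a)
        object.__setattr__(self, "exponent_b", b)

    def __str__(self) -> str:
        return sci2(self.value)


def fraction(n_allowed: int, n_total: int, label: str = ""
             ) -> ConstraintFraction:
    """Exact constraint fraction N_x / N_tot with its rendered form."""
    return ConstraintFraction(label=label, n_allowed=int(n_allowed),
                              n_total=int(n_total))


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def _case_fractions(counts) -> Mapping[str, float]:
    if isinstance(counts, ViabilityCounts):
        return counts.fractions()
    return dict(counts)


def _size_columns(spec: MotifSpec) -> dict:
    h, l = spec.helix_sizes, spec.loop_sizes
    if spec.motif_type == "PK":
        return {"H1": h[0], "L1": l[0], "L2": l[1], "L3": l[2], "H2": h[1]}
    out = {f"H{i + 1}": v for i, v in enumerate(h)}
    out.update({f"L{i + 1}": v for i, v in enumerate(l)})
    return out


def summarize_cases(case_list: Sequence[tuple]) -> pd.DataFrame:
    """Per-case constraint-fraction table with an Average row.

    ``case_list`` holds (name, MotifSpec, counts) triples, where ``counts``
    is a :class:`ViabilityCounts` or a mapping from loop-subset label to a
    fraction value.  All cases must share one motif type.  The Average row
    is the arithmetic mean of the raw (unrounded) values; use
    :func:`sci2` on any cell for the rendered two-significant-figure form.
    """
    if not case_list:
        raise ValueError("case_list must be nonempty")
    types = {spec.motif_type for _, spec, _ in case_list}
    if len(types) > 1:
        raise ValueError(f"mixed motif types in one table: {sorted(types)}")
    motif_type = types.pop()
    columns = PK_COLUMNS if motif_type == "PK" else KISS_COLUMNS
    rows = []
    for name, spec, counts in case_list:
        fr = _case_fractions(counts)
        row = {"name": name, "size": spec.size_string}
        row.update(_size_columns(spec))
        for col, label in columns.items():
            row[col] = fr[label]
        rows.append(row)
    df = pd.DataFrame(rows)
    avg = {"name": "Average", "size": ""}
    for col in columns:
        avg[col] = df[col].mean()
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def render_table(df: pd.DataFrame) -> pd.DataFrame:
    """Rendered copy of a summary table (fractions as "4.3E-3" strings)."""
    out = df.copy()
    for col in out.columns:
        if col.startswith("F_"):
            out[col] = [sci2(v) if pd.notna(v) else "" for v in out[col]]
    return out


def group_average(table: pd.DataFrame, column: str, by: str) -> pd.Series:
    """Arithmetic mean of one F column grouped by a size key (e.g. L2).

    The Average row, if present, is excluded from the grouping.
    """
    df = table
    if "name" in df.columns:
        df = df[df["name"] != "Average"]
    if by not in df.columns:
        raise KeyError(f"group key {by!r} not in table")
    if df[by].isna().any():
        raise ValueError(f"group key {by!r} undefined for some rows")
    return df.groupby(by)[column].mean()


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

_PK_SIZE_KEYS = ("H1", "L1", "L2", "L3", "H2")


def _pk_spec(sizes: Mapping[str, int]) -> MotifSpec:
    return MotifSpec("PK", [sizes["H1"], sizes["H2"]],
                     [sizes["L1"], sizes["L2"], sizes["L3"]])


@dataclass
class LandscapeGrid:
    """Averaged-fraction landscape over two swept size variables."""

    axis1: str
    axis2: str
    values1: list
    values2: list
    cells: np.ndarray               # mean F, shape (len(values1), len(values2))
    averaging_set: dict             # marginalized size name -> values
    subset: str = "123"

    def __post_init__(self):
        if np.any((self.cells < 0) | (self.cells > 1)):
            raise ValueError("landscape cells must be fractions in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=pd.Index(self.values1,
                                                       name=self.axis1),
                            columns=pd.Index(self.values2, name=self.axis2))

    def ab_frame(self) -> pd.DataFrame:
        """(mantissa, exponent) rendering of each cell, for color maps keyed
        on the exponent b or the mantissa a of F."""
        rec = [[mantissa_exponent(v) for v in row] for row in self.cells]
        return pd.DataFrame(rec, index=self.to_frame().index,
                            columns=self.to_frame().columns)


def landscape(motif_type: str,
              swept: tuple[str, str],
              ranges: tuple[Iterable[int], Iterable[int]],
              marginalized: Mapping[str, Iterable[int]],
              config: RunConfig = REDUCED_PROFILE,
              subset: str = "123") -> LandscapeGrid:
    """Averaged constraint-fraction grid over two swept size variables.

    For every cell (v1, v2) of the swept axes the fraction for ``subset``
    (default the full PK subset, F_PK) is computed by exhaustive enumeration
    for each combination of the marginalized sizes and averaged
    arithmetically.  Size keys are H1, L1, L2, L3, H2.
    """
    if motif_type != "PK":
        raise ValueError("landscape sweeps are implemented for PK motifs")
    ax1, ax2 = swept
    vals1, vals2 = list(ranges[0]), list(ranges[1])
    if not vals1 or not vals2:
        raise ValueError("swept ranges must be nonempty")
    marg = {k: list(v) for k, v in marginalized.items()}
    need = set(_PK_SIZE_KEYS) - {ax1, ax2}
    if set(marg) != need:
        raise ValueError(f"marginalized set must cover {sorted(need)}")
    cells = np.empty((len(vals1), len(vals2)))
    marg_keys = list(marg)
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            fs = []
            for combo in itertools.product(*(marg[k] for k in marg_keys)):
                sizes = dict(zip(marg_keys, combo))
                sizes[ax1], sizes[ax2] = v1, v2
                vc = count_pk(_pk_spec(sizes), config=config)
                fs.append(vc.fraction(subset))
            cells[i, j] = float(np.mean(fs))
    return LandscapeGrid(axis1=ax1, axis2=ax2, values1=vals1, values2=vals2,
                         cells=cells, averaging_set=marg, subset=subset)
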