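"""Grouped binary encoding of marker-selection masks.

The marker space is cut into consecutive groups of at most ``step`` markers.
One non-negative integer per group encodes the inclusion flags of its
markers: the integer written in binary, zero-padded to the group length,
most-significant bit first, with the leftmost bit mapping to the group's
lowest marker index.  The optimizer therefore searches a short vector of
bounded integers instead of thousands of independent bits.

Every group may be empty except the last, whose minimum value of 1
guarantees that at least one marker is always selected.

Worked example (25 markers, step 10): group lengths [10, 10, 5], bounds
low = [0, 0, 1] and high = [1023, 1023, 31]; the integer vector [3, 5, 2]
expands to the bit strings 0000000011 | 0000000101 | 00010 and selects the
1-based marker columns {9, 10, 18, 20, 24}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureGrouping", "SelectionMask", "build_grouping", "decode_selection", "encode_mask"]

# 2**step - 1 must stay an exact 64-bit integer
_MAX_STEP = 62


@dataclass(frozen=True)
class FeatureGrouping:
    """Group structure of the encoding: lengths and per-group integer bounds."""

    num_features: int
    step: int
    group_lengths: tuple[int, ...]
    min_select: tuple[int, ...]
    max_select: tuple[int, ...]

    @property
    def n_groups(self) -> int:
        return len(self.group_lengths)


@dataclass(frozen=True)
class SelectionMask:
    """Boolean inclusion flags over the marker columns (True = selected)."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        if flags.ndim != 1 or flags.size == 0:
            raise ValueError("flags must be a non-empty 1-D boolean vector")
        if not flags.any():
            raise ValueError("a selection mask must select at least one marker")
        object.__setattr__(self, "flags", flags)

    @property
    def n_selected(self) -> int:
        return int(self.flags.sum())

    @property
    def selected_indices(self) -> list[int]:
        """1-based selected column indices (reporting convention)."""
        return [int(i) + 1 for i in np.flatnonzero(self.flags)]


def build_grouping(num_features: int, step: int) -> FeatureGrouping:
    """Partition ``num_features`` markers into groups of size ``step``.

    The final group holds the remainder ``num_features mod step`` when that
    is non-zero; when the division is exact there is no partial group and
    the minimum-selection constraint of 1 attaches to the (full-size) last
    group.
    """
    if num_features < 1:
        raise ValueError("num_features must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if step > _MAX_STEP:
        raise ValueError(
            f"step must be <= {_MAX_STEP} so group bounds stay exact 64-bit "
            "integers; use more groups instead of larger ones"
        )
    n_full, remainder = divmod(num_features, step)
    lengths = [step] * n_full
    if remainder:
        lengths.append(remainder)
    max_select = tuple(2**length - 1 for length in lengths)
    min_select = tuple([0] * (len(lengths) - 1) + [1])
    return FeatureGrouping(
        num_features=num_features,
        step=step,
        group_lengths=tuple(lengths),
        min_select=min_select,
        max_select=max_select,
    )


def decode_selection(group_values, grouping: FeatureGrouping) -> SelectionMask:
    """Expand per-group integers into the concatenated marker mask.

    Each integer is written in binary padded to the group length, MSB first;
    the leftmost bit maps to the group's first (lowest-index) marker.
    Values outside ``[min_select, max_select]`` are rejected with the group
    named.
    """
    values = [int(v) for v in group_values]
    if len(values) != grouping.n_groups:
        raise ValueError(
            f"expected {grouping.n_groups} group values, got {len(values)}"
        )
    flags = np.zeros(grouping.num_features, dtype=bool)
    offset = 0
    for g, (value, length) in enumerate(zip(values, grouping.group_lengths)):
        lo, hi = grouping.min_select[g], grouping.max_select[g]
        if not lo <= value <= hi:
            raise ValueError(
                f"group {g}: value {value} outside allowed range [{lo}, {hi}]"
            )
        bits = format(value, f"0{length}b")
        flags[offset : offset + length] = [b == "1" for b in bits]
        offset += length
    return SelectionMask(flags=flags)


def encode_mask(mask: SelectionMask | np.ndarray, grouping: FeatureGrouping) -> list[int]:
    """Exact inverse of :func:`decode_selection`."""
    flags = mask.flags if isinstance(mask, SelectionMask) else np.asarray(mask, dtype=bool)
    if flags.size != grouping.num_features:
        raise ValueError(
            f"mask length {flags.size} does not match {grouping.num_features} features"
        )
    values: list[int] = []
    offset = 0
    for length in grouping.group_lengths:
        chunk = flags[offset : offset + length]
        values.append(int("".join("1" if b else "0" for b in chunk), 2))
        offset += length
    if values[-1] < grouping.min_select[-1]:
        raise ValueError("last group selects no marker, violating the minimum of 1")
    return values
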