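"""bedGraph export/import for coverage and ratio tracks.

All tracks live on the single collapsed unit; adjacent equal values are
merged into one interval, the canonical bedGraph form.
"""

from __future__ import annotations

import numpy as np

from .annotation import UNIT_NAME


def write_bedgraph(values, path, unit_name: str = UNIT_NAME) -> None:
    vals = np.asarray(values)
    if hasattr(values, "values"):
        vals = np.asarray(values.values)
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[start]:
                v = vals[start]
                txt = f"{int(v)}" if float(v).is_integer() else f"{float(v):.6g}"
                fh.write(f"{unit_name}\t{start}\t{i}\t{txt}\n")
                start = i


def read_bedgraph(path, unit_length: int | None = None) -> np.ndarray:
    """Read a single-sequence bedGraph back into a dense per-base vector."""
    intervals: list[tuple[int, int, float]] = []
    max_end = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph fields")
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            intervals.append((start, end, value))
            max_end = max(max_end, end)
    L = unit_length if unit_length is not None else max_end
    out = np.zeros(L, dtype=float)
    for start, end, value in intervals:
        if end > L:
            raise ValueError(f"{path}: interval end {end} beyond unit length {L}")
        out[start:end] = value
    return out
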