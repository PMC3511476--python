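"""ms-style haplotype block I/O.

A block is the classic text layout of coalescent simulators::

    //
    segsites: 4
    positions: 0.031 0.22 0.47 0.91
    0010
    1100
    ...

with one 0/1 row per sample (ancestral state 0).  Positions are fractions
of the window length; :func:`write_ms` converts integer site coordinates
using the window length, and :func:`read_ms` converts back (rounding down).
Missing alleles may be encoded as ``?`` and are returned as -1.
"""

from __future__ import annotations

import io

import numpy as np


def write_ms(matrix: np.ndarray, sites: list[int], length: int,
             path_or_file, header: str | None = None) -> None:
    """Write one haplotype block; ``matrix`` is samples x sites (0/1/-1)."""
    close = False
    fh = path_or_file
    if not hasattr(fh, "write"):
        fh = open(fh, "w")
        close = True
    try:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        fh.write("//\n")
        fh.write(f"segsites: {len(sites)}\n")
        if sites:
            pos = " ".join(f"{(s + 0.5) / length:.6f}" for s in sites)
            fh.write(f"positions: {pos}\n")
        for row in matrix:
            fh.write("".join("?" if v < 0 else str(int(v)) for v in row) + "\n")
    finally:
        if close:
            fh.close()


def read_ms(path_or_file, length: int | None = None
            ) -> list[tuple[np.ndarray, list]]:
    """Read all blocks; returns (matrix, positions) per block.

    Positions are integer site coordinates when ``length`` is given, else
    the raw fractions.
    """
    close = False
    fh = path_or_file
    if isinstance(fh, str):
        fh = open(fh)
        close = True
    elif isinstance(fh, bytes):  # pragma: no cover
        fh = io.StringIO(fh.decode())
    try:
        blocks = []
        lines = iter(fh.read().splitlines())
        cur_rows: list[list[int]] = []
        positions: list = []
        segsites = None

        def flush():
            nonlocal cur_rows, positions, segsites
            if segsites is None:
                return
            mat = np.array(cur_rows, dtype=np.int8) if cur_rows else \
                np.zeros((0, segsites), dtype=np.int8)
            blocks.append((mat, positions))
            cur_rows, positions, segsites = [], [], None

        for line in lines:
            line = line.strip()
            if line.startswith("//"):
                flush()
                continue
            if line.startswith("segsites:"):
                segsites = int(line.split(":")[1])
                if segsites == 0:
                    positions = []
                continue
            if line.startswith("positions:"):
                fracs = [float(tok) for tok in line.split(":")[1].split()]
                if length is not None:
                    positions = [min(int(f * length), length - 1) for f in fracs]
                else:
                    positions = fracs
                continue
            if segsites is not None and line and set(line) <= set("01?"):
                cur_rows.append([-1 if ch == "?" else int(ch) for ch in line])
        flush()
        return blocks
    finally:
        if close:
            fh.close()
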