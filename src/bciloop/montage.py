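"""Sensorimotor 10-20 montage, Laplacian neighborhoods and region definitions.

The default montage is the 16-channel sensorimotor grid used for motor-imagery
decoding: three rows (FC, C, CP) over five columns (3, 1, z, 2, 4), plus one
extra channel (Fz by default) that carries no Laplacian neighbors and passes
through the spatial filter unchanged.
"""

from __future__ import annotations

# Row-major grid order: FC row, C row, CP row, then the extra channel.
GRID_ROWS = ("FC", "C", "CP")
GRID_COLS = ("3", "1", "z", "2", "4")

SENSORIMOTOR_GRID: tuple[str, ...] = tuple(
    f"{row}{col}" for row in GRID_ROWS for col in GRID_COLS
)

#: Default 16-channel montage (15 sensorimotor grid sites + Fz).
DEFAULT_CHANNELS: tuple[str, ...] = SENSORIMOTOR_GRID + ("Fz",)

#: Topographic regions used for discriminancy aggregates.
MEDIAL_CHANNELS: tuple[str, ...] = ("FCz", "Cz", "CPz")
LATERAL_CHANNELS: tuple[str, ...] = ("FC3", "C3", "CP3", "FC4", "C4", "CP4")

#: Spectral regions (Hz, inclusive bounds on 2 Hz band centers).
MU_BAND: tuple[float, float] = (8.0, 14.0)
BETA_BAND: tuple[float, float] = (22.0, 32.0)


def default_laplacian_map(
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> dict[str, tuple[str, ...]]:
    """Orthogonal nearest-neighbor Laplacian map on the FC/C/CP grid.

    Each grid channel's neighbors are its horizontal and vertical
    nearest neighbors that are present in ``channels`` (e.g. Cz has
    FCz, CPz, C1 and C2). Channels off the grid get an empty neighbor
    list and are passed through the spatial filter unchanged.
    """
    present = set(channels)
    lap: dict[str, tuple[str, ...]] = {}
    for ch in channels:
        row = col = None
        for r in GRID_ROWS:
            if ch.startswith(r) and ch[len(r):] in GRID_COLS:
                # "CP3" startswith "C" too; require exact row+col split
                row, col = r, ch[len(r):]
        if row is None:
            lap[ch] = ()
            continue
        ri, ci = GRID_ROWS.index(row), GRID_COLS.index(col)
        neigh = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r2, c2 = ri + dr, ci + dc
            if 0 <= r2 < len(GRID_ROWS) and 0 <= c2 < len(GRID_COLS):
                cand = f"{GRID_ROWS[r2]}{GRID_COLS[c2]}"
                if cand in present:
                    neigh.append(cand)
        lap[ch] = tuple(neigh)
    return lap


def validate_laplacian_map(
    lap: dict[str, tuple[str, ...]], channels: tuple[str, ...]
) -> None:
    """Raise ``ValueError`` on unknown channels or self-neighborhoods."""
    present = set(channels)
    for ch, neigh in lap.items():
        if ch not in present:
            raise ValueError(f"Laplacian map channel {ch!r} not in montage")
        for n in neigh:
            if n not in present:
                raise ValueError(
                    f"Laplacian neighbor {n!r} of {ch!r} not in montage"
                )
            if n == ch:
                raise ValueError(f"channel {ch!r} is its own neighbor")
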