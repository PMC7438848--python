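"""The 19-channel international 10-20 scalp montage used throughout.

Channel order is fixed (frontal to occipital, left to right) and every
matrix-valued object in the package indexes its rows/columns in this order.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Mapping

#: Canonical channel order for the 19-electrode 10-20 montage.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

CHANNEL_INDEX: Mapping[str, int] = {name: i for i, name in enumerate(CHANNELS)}

# Nearest-neighbor scalp adjacency on the 10-20 layout (undirected edges).
_EDGES: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("Fp1", "F7"), ("Fp1", "F3"),
    ("Fp2", "F4"), ("Fp2", "F8"),
    ("F7", "F3"), ("F7", "T3"),
    ("F3", "Fz"), ("F3", "C3"),
    ("Fz", "F4"), ("Fz", "Cz"),
    ("F4", "F8"), ("F4", "C4"),
    ("F8", "T4"),
    ("T3", "C3"), ("T3", "T5"),
    ("C3", "Cz"), ("C3", "P3"),
    ("Cz", "C4"), ("Cz", "Pz"),
    ("C4", "T4"), ("C4", "P4"),
    ("T4", "T6"),
    ("T5", "P3"), ("T5", "O1"),
    ("P3", "Pz"), ("P3", "O1"),
    ("Pz", "P4"),
    ("P4", "T6"), ("P4", "O2"),
    ("T6", "O2"),
    ("O1", "O2"),
)

ADJACENCY: dict[str, frozenset[str]] = {name: frozenset() for name in CHANNELS}
for _a, _b in _EDGES:
    ADJACENCY[_a] = ADJACENCY[_a] | {_b}
    ADJACENCY[_b] = ADJACENCY[_b] | {_a}


def normalize_name(raw: str) -> str | None:
    """Map a raw channel label to its canonical 10-20 name, or None.

    Matching is case- and whitespace-insensitive and strips common EDF
    decorations such as an ``EEG `` prefix or a ``-REF``/``-LE`` suffix.
    """
    s = raw.strip().upper().replace(" ", "")
    if s.startswith("EEG"):
        s = s[3:]
    for suffix in ("-REF", "-LE", "-AVG", "-A1", "-A2"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    lookup = {name.upper(): name for name in CHANNELS}
    return lookup.get(s)


def graph_distances(sources: Iterable[str]) -> dict[str, int]:
    """Multi-source BFS hop count from ``sources`` over the scalp adjacency.

    Unknown channel names raise; unreachable channels cannot occur (the
    adjacency graph is connected).
    """
    sources = list(sources)
    for s in sources:
        if s not in CHANNEL_INDEX:
            raise ValueError(f"unknown channel name: {s!r}")
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        node = queue.popleft()
        for nb in ADJACENCY[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return dist
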