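"""Square fiducial-marker dictionary: 4x4-bit payloads inside a black border.

A marker is a 6x6 module grid: a one-module black border surrounding a 4x4
payload of black/white cells (bit 1 = white).  Printed markers add a white
quiet zone around the border so the black frame stays detectable against
dark fur or flooring.

The dictionary is generated deterministically (fixed internal seed) under
two constraints that make detection unambiguous:

* every pairwise Hamming distance between codes — including all four
  rotations of each code — is at least 4, so a one-bit read error cannot
  turn one marker into another;
* every code keeps distance >= 4 from its own rotations, so the detected
  orientation (hence the marker's heading) is never ambiguous.

Codes are 16-bit integers, payload bits read row-major from the top-left
cell of the upright pattern.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

GRID_BITS = 4  # payload is GRID_BITS x GRID_BITS
BORDER_MODULES = 1
MARKER_MODULES = GRID_BITS + 2 * BORDER_MODULES  # 6
QUIET_MODULES = 1  # white quiet zone width when rendered

_DICT_SEED = 20240301
_MIN_HAMMING = 4


def bits_to_code(bits: np.ndarray) -> int:
    """Row-major 4x4 bit matrix -> 16-bit integer code."""
    flat = np.asarray(bits, dtype=int).reshape(-1)
    return int(sum(b << i for i, b in enumerate(flat)))


def code_to_bits(code: int) -> np.ndarray:
    """16-bit integer code -> row-major 4x4 bit matrix."""
    return np.array([(code >> i) & 1 for i in range(GRID_BITS ** 2)],
                    dtype=np.uint8).reshape(GRID_BITS, GRID_BITS)


def rotations(bits: np.ndarray) -> list[np.ndarray]:
    """The four in-plane rotations of a payload (0, 90, 180, 270 deg CCW)."""
    return [np.rot90(bits, k) for k in range(4)]


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.sum(a != b))


@lru_cache(maxsize=4)
def marker_dictionary(n_markers: int = 50) -> list[np.ndarray]:
    """Generate the standard n-marker 4x4 dictionary.

    Deterministic: the same list on every call.  Returns payload bit
    matrices indexed by marker ID.
    """
    rng = np.random.default_rng(_DICT_SEED)
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n_markers:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("dictionary generation failed to converge")
        cand = rng.integers(0, 2, size=(GRID_BITS, GRID_BITS)).astype(np.uint8)
        n_white = int(cand.sum())
        if n_white < 4 or n_white > 12:  # avoid near-uniform patterns
            continue
        cand_rots = rotations(cand)
        # orientation must be resolvable from the payload alone
        if any(_hamming(cand, r) < _MIN_HAMMING for r in cand_rots[1:]):
            continue
        ok = True
        for prev in chosen:
            for r in rotations(prev):
                if any(_hamming(c, r) < _MIN_HAMMING for c in cand_rots):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            chosen.append(cand)
    return chosen


def marker_bitmap(marker_id: int, n_markers: int = 50) -> np.ndarray:
    """Full 6x6 module grid (border + payload) for a marker ID; 1 = white."""
    dictionary = marker_dictionary(n_markers)
    if not (0 <= marker_id < len(dictionary)):
        raise KeyError(f"marker id {marker_id} outside dictionary of "
                       f"{len(dictionary)}")
    grid = np.zeros((MARKER_MODULES, MARKER_MODULES), dtype=np.uint8)
    grid[BORDER_MODULES:-BORDER_MODULES,
         BORDER_MODULES:-BORDER_MODULES] = dictionary[marker_id]
    return grid


@lru_cache(maxsize=4)
def rotation_code_table(n_markers: int = 50) -> dict[int, tuple[int, int]]:
    """Lookup: payload code (any rotation) -> (marker_id, rotation k).

    k is the number of 90-degree CCW rotations taking the canonical
    payload to the observed one.
    """
    table: dict[int, tuple[int, int]] = {}
    for mid, bits in enumerate(marker_dictionary(n_markers)):
        for k in range(4):
            table[bits_to_code(np.rot90(bits, k))] = (mid, k)
    return table
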