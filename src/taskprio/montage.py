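"""64-channel 10-10 montage: positions, mirror pairs, posterior cluster.

Positions are built on a unit sphere (x right, y anterior, z up): the outer
ring Fpz--T7--Oz lies on the equator with 20 slots every 18 degrees, interior
rows are great-circle interpolations between their midline anchor and the
ring, and the 9/10-labelled channels sit 18 degrees below their 7/8
neighbours.  The layout is mirror-symmetric about the midsagittal plane,
which is what electrode pairing and adjacency need; it is not a digitised
head model.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

# ring channels front -> right -> back -> left, 18 deg apart (azimuth from
# +y, clockwise toward +x when seen from above)
_RING = [
    "Fpz", "Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2",
    "Oz", "O1", "PO7", "P7", "TP7", "T7", "FT7", "F7", "AF7", "Fp1",
]

# midline anchors: polar angle from the vertex (degrees); positive y = front
_MIDLINE = {
    "Fpz": 90.0, "AFz": 67.5, "Fz": 45.0, "FCz": 22.5, "Cz": 0.0,
    "CPz": 22.5, "Pz": 45.0, "POz": 67.5, "Oz": 90.0,
}
_FRONT = {"Fpz", "AFz", "Fz", "FCz"}

# interior rows: (midline anchor, left ring anchor, right ring anchor)
_ROWS = {
    "AF": ("AFz", "AF7", "AF8"),
    "F": ("Fz", "F7", "F8"),
    "FC": ("FCz", "FT7", "FT8"),
    "C": ("Cz", "T7", "T8"),
    "CP": ("CPz", "TP7", "TP8"),
    "P": ("Pz", "P7", "P8"),
    "PO": ("POz", "PO7", "PO8"),
}

#: all left/right mirror pairs of the montage (left first)
MIRROR_PAIRS: list[tuple[str, str]] = [
    ("Fp1", "Fp2"), ("AF7", "AF8"), ("AF3", "AF4"),
    ("F7", "F8"), ("F5", "F6"), ("F3", "F4"), ("F1", "F2"),
    ("FT9", "FT10"), ("FT7", "FT8"),
    ("FC5", "FC6"), ("FC3", "FC4"), ("FC1", "FC2"),
    ("T7", "T8"), ("C5", "C6"), ("C3", "C4"), ("C1", "C2"),
    ("TP9", "TP10"), ("TP7", "TP8"),
    ("CP5", "CP6"), ("CP3", "CP4"), ("CP1", "CP2"),
    ("P7", "P8"), ("P5", "P6"), ("P3", "P4"), ("P1", "P2"),
    ("PO9", "PO10"), ("PO7", "PO8"), ("PO3", "PO4"),
    ("O1", "O2"),
]

#: posterior electrode pairs entering the pooled lateralization curve
POSTERIOR_PAIRS: list[tuple[str, str]] = [
    ("T7", "T8"), ("C5", "C6"), ("C3", "C4"), ("C1", "C2"),
    ("TP9", "TP10"), ("TP7", "TP8"),
    ("CP5", "CP6"), ("CP3", "CP4"), ("CP1", "CP2"),
    ("P7", "P8"), ("P5", "P6"), ("P3", "P4"), ("P1", "P2"),
    ("PO7", "PO8"), ("PO3", "PO4"), ("PO9", "PO10"),
    ("O1", "O2"),
]


def _sph(polar_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector from vertex polar angle and azimuth (0 = front)."""
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(az_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    return (np.sin((1 - frac) * omega) * a + np.sin(frac * omega) * b) / np.sin(omega)


def build_positions() -> pd.DataFrame:
    """Construct the 64-channel montage geometrically.

    Returns a DataFrame indexed by channel name with columns x, y, z
    (unit sphere).  ``load_montage`` reads the shipped copy of this table.
    """
    pos: dict[str, np.ndarray] = {}
    ring_vec: dict[str, np.ndarray] = {}
    for i, name in enumerate(_RING):
        v = _sph(90.0, 18.0 * i)
        ring_vec[name] = v
        pos[name] = v
    anchors = {
        m: _sph(th, 0.0 if m in _FRONT else 180.0) for m, th in _MIDLINE.items()
    }
    for row, (mid, left, right) in _ROWS.items():
        m = anchors[mid]
        for n, frac in [(1, 0.25), (3, 0.5), (5, 0.75)]:
            pos[f"{row}{n}"] = _slerp(m, ring_vec[left], frac)
            pos[f"{row}{n + 1}"] = _slerp(m, ring_vec[right], frac)
    # channels 18 deg below the outer ring, same azimuth as their 7/8 partner
    for low, ring in [("FT9", "FT7"), ("FT10", "FT8"), ("TP9", "TP7"),
                      ("TP10", "TP8"), ("PO9", "PO7"), ("PO10", "PO8")]:
        v = ring_vec[ring]
        az = np.arctan2(v[0], v[1])
        pos[low] = _sph(108.0, np.rad2deg(az))
    # midline electrodes actually present in the cap
    for m in ("Fz", "Cz", "CPz", "Pz", "POz"):
        pos[m] = anchors[m]
    # drop virtual anchors / keep the 64 real channels
    keep = set(sum([list(p) for p in MIRROR_PAIRS], [])) | {
        "Fz", "Cz", "CPz", "Pz", "POz", "Oz",
    }
    # the AF row only has AF3/AF4 besides AF7/AF8; FC/CP rows have 1..6; the
    # construction above creates AF1/AF2/AF5/AF6 etc. as a side effect
    table = {k: v for k, v in pos.items() if k in keep}
    df = pd.DataFrame(table, index=["x", "y", "z"]).T.sort_index()
    df.index.name = "channel"
    if len(df) != 64:
        raise RuntimeError(f"montage construction yielded {len(df)} channels")
    return df


def load_montage() -> pd.DataFrame:
    """Load the shipped montage table (channel -> x, y, z on a unit sphere)."""
    with resources.files("taskprio").joinpath("montage_1010.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="channel")
    return df


def channel_names() -> list[str]:
    return list(load_montage().index)


def pair_indices(names: list[str], pairs: list[tuple[str, str]] | None = None) -> np.ndarray:
    """Map (left, right) channel-name pairs to integer index pairs."""
    pairs = POSTERIOR_PAIRS if pairs is None else pairs
    lookup = {n: i for i, n in enumerate(names)}
    missing = [p for p in pairs for c in p if c not in lookup]
    if missing:
        raise KeyError(f"channels missing from montage: {missing}")
    return np.array([(lookup[l], lookup[r]) for l, r in pairs], dtype=int)
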