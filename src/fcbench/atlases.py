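"""Atlas presets.

Two synthetic parcellations mirror the granularity of the atlases most
common in structure-function studies: a 68-parcel anatomical atlas
("dk_like", Desikan-Killiany granularity) and a 200-parcel functional atlas
("schaefer_like"). Parcel counts per Yeo-7 system are chosen with roughly
realistic proportions (association cortex — default mode and frontoparietal
systems — claims the largest share; limbic the smallest).
"""

from __future__ import annotations

import numpy as np

from .core import Atlas, YEO7_NETWORKS

# parcels per network, left+right hemisphere combined
_DK_COUNTS = {"VN": 8, "SMN": 10, "DAN": 8, "VAN": 8, "LSN": 6, "FPN": 12, "DMN": 16}
_SCHAEFER_COUNTS = {
    "VN": 30,
    "SMN": 32,
    "DAN": 26,
    "VAN": 24,
    "LSN": 12,
    "FPN": 30,
    "DMN": 46,
}


def _build(counts: dict, name: str) -> Atlas:
    labels, networks = [], []
    for net in YEO7_NETWORKS:
        c = counts[net]
        for i in range(c):
            hemi = "L" if i < (c + 1) // 2 else "R"
            labels.append(f"{hemi}_{net}_{i % ((c + 1) // 2) + 1}")
            networks.append(net)
    return Atlas(labels=tuple(labels), networks=tuple(networks), name=name)


def dk_like() -> Atlas:
    """68-parcel anatomical-granularity preset."""
    return _build(_DK_COUNTS, "dk_like")


def schaefer_like() -> Atlas:
    """200-parcel functional-granularity preset."""
    return _build(_SCHAEFER_COUNTS, "schaefer_like")


def toy(p: int) -> Atlas:
    """Small atlas for fast experiments: p parcels spread over all 7 systems
    proportionally to the dk_like layout."""
    if p < 7:
        raise ValueError("toy atlas needs at least 7 parcels (one per network)")
    weights = np.array([_DK_COUNTS[n] for n in YEO7_NETWORKS], dtype=float)
    counts = np.maximum(1, np.floor(p * weights / weights.sum()).astype(int))
    while counts.sum() < p:
        counts[np.argmax(weights / counts)] += 1
    while counts.sum() > p:
        big = np.argmax(counts)
        counts[big] -= 1
    return _build(dict(zip(YEO7_NETWORKS, counts.tolist())), f"toy{p}")


PRESETS = {"dk_like": dk_like, "schaefer_like": schaefer_like}


def get_atlas(name: str) -> Atlas:
    if name in PRESETS:
        return PRESETS[name]()
    if name.startswith("toy"):
        return toy(int(name[3:]))
    raise KeyError(f"unknown atlas preset {name!r}; known: {sorted(PRESETS)} or toyN")
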