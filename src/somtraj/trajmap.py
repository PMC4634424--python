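"""Posture sequences and trajectory maps.

A motion trajectory becomes a sequence of basin ids (one per frame), adjacent
repetitions are collapsed away, and the collapsed sequence is rendered onto
the posture map as a fixed-size gray image: the region of each visited basin
is shaded by its first-appearance order, darker meaning earlier, with
unvisited basins left white (255).  Per-basin binary "appearance strings"
record every position of the basin in the collapsed sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .posture_map import PostureMap, assign_basin

__all__ = [
    "DEFAULT_G_MAX",
    "PostureSequence",
    "TrajectoryMap",
    "encode",
    "collapse_repetitions",
    "appearance_strings",
    "render_trajectory_map",
    "write_pgm",
]

#: Darkest-to-lightest span of visited-basin shades; kept below 255 so every
#: visited basin is distinguishable from unvisited white.
DEFAULT_G_MAX = 200


@dataclass
class PostureSequence:
    """Ordered basin ids; ``collapsed`` means no two adjacent ids are equal."""

    symbols: list[int]
    collapsed: bool = False

    def __post_init__(self) -> None:
        self.symbols = [int(s) for s in self.symbols]
        if self.collapsed:
            for a, b in zip(self.symbols, self.symbols[1:]):
                if a == b:
                    raise ValueError("collapsed sequence has adjacent repetitions")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


@dataclass
class TrajectoryMap:
    """Fixed-size gray rendering of a collapsed posture sequence."""

    image: np.ndarray  # (M, N) uint8, 255 = unvisited
    appearance: dict[int, str] = field(default_factory=dict)
    sequence: list[int] = field(default_factory=list)

    def to_json(self, path) -> None:
        obj = {
            "M": int(self.image.shape[0]),
            "N": int(self.image.shape[1]),
            "image": self.image.ravel().tolist(),
            "appearance": {str(k): v for k, v in self.appearance.items()},
            "sequence": list(self.sequence),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "TrajectoryMap":
        with open(path) as fh:
            obj = json.load(fh)
        img = np.array(obj["image"], dtype=np.uint8).reshape(obj["M"], obj["N"])
        return cls(
            image=img,
            appearance={int(k): v for k, v in obj["appearance"].items()},
            sequence=[int(s) for s in obj["sequence"]],
        )


def encode(pmap: PostureMap, frames) -> PostureSequence:
    """Raw per-frame basin sequence (one symbol per frame, in order)."""
    frames = list(frames)
    if not frames:
        raise ValueError("cannot encode an empty trajectory")
    return PostureSequence([assign_basin(pmap, np.asarray(x)) for x in frames])


def collapse_repetitions(seq: PostureSequence) -> PostureSequence:
    """Delete adjacent duplicate symbols; order preserved; idempotent."""
    out: list[int] = []
    for s in seq.symbols:
        if not out or out[-1] != s:
            out.append(s)
    return PostureSequence(out, collapsed=True)


def appearance_strings(seq: PostureSequence) -> dict[int, str]:
    """Per-basin indicator string over the collapsed sequence positions."""
    if not seq.collapsed:
        raise ValueError("appearance strings are defined on collapsed sequences")
    return {
        b: "".join("1" if s == b else "0" for s in seq.symbols)
        for b in dict.fromkeys(seq.symbols)
    }


def render_trajectory_map(
    pmap: PostureMap, seq: PostureSequence, g_max: int = DEFAULT_G_MAX
) -> TrajectoryMap:
    """Shade each visited basin's region by first-appearance order.

    The D distinct basins, ranked by first appearance, get evenly spaced
    grays round(r * g_max / max(D-1, 1)) for rank r = 0..D-1: the first is
    black, the last g_max, revisits keep their first shade ("151" shades its
    two basins 0 and g_max).  Unvisited basins stay white (255).
    """
    if not seq.collapsed:
        raise ValueError("render expects a collapsed sequence")
    if len(seq) == 0:
        raise ValueError("cannot render an empty sequence")
    valid = set(int(v) for v in np.unique(pmap.labeling))
    for s in seq.symbols:
        if s not in valid:
            raise ValueError(f"unknown basin id {s}")
    image = np.full(pmap.labeling.shape, 255, dtype=np.uint8)
    ranked = list(dict.fromkeys(seq.symbols))  # distinct, first-appearance order
    denom = max(len(ranked) - 1, 1)
    for r, b in enumerate(ranked):
        shade = int(round(r * g_max / denom))
        image[pmap.labeling == b] = shade
    return TrajectoryMap(
        image=image, appearance=appearance_strings(seq), sequence=list(seq.symbols)
    )


def write_pgm(image: np.ndarray, path) -> None:
    """Plain-text (P2) PGM export for visual inspection."""
    img = np.asarray(image)
    with open(path, "w") as fh:
        fh.write(f"P2\n{img.shape[1]} {img.shape[0]}\n255\n")
        for row in img:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
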