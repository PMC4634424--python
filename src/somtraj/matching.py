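"""Template building (multi-sequence LCS) and trajectory-map classification.

One template per exercise is distilled from several recorded instances: each
instance's collapsed posture sequence enters an exact multi-sequence longest
common subsequence, and the LCS is rendered as the template trajectory map.
An unknown trajectory map is compared to every template by normalized image
correlation (Pearson correlation of the pixel values about their means) and
assigned to the best-scoring template, unless the best score falls below the
library's rejection threshold.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field

import numpy as np

from .posture_map import PostureMap
from .trajmap import PostureSequence, TrajectoryMap, collapse_repetitions, encode, render_trajectory_map

__all__ = [
    "DEFAULT_THRESHOLD",
    "MAX_LCS_SEQUENCES",
    "MAX_LCS_LENGTH",
    "TemplateEntry",
    "TemplateLibrary",
    "ClassificationResult",
    "lcs_pair",
    "lcs_multi",
    "build_template",
    "similarity",
    "classify",
]

DEFAULT_THRESHOLD = 0.5
MAX_LCS_SEQUENCES = 6
MAX_LCS_LENGTH = 64
_MAX_LCS_STATES = 50_000_000  # memo-table guard for the k-dimensional DP


def lcs_pair(a: PostureSequence, b: PostureSequence) -> PostureSequence:
    """Longest common subsequence of two sequences by the classic DP.

    Backtracking is deterministic: prefer the diagonal match, then the cell
    above, then the left cell.
    """
    sa, sb = a.symbols, b.symbols
    la, lb = len(sa), len(sb)
    dp = np.zeros((la + 1, lb + 1), dtype=int)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            if sa[i - 1] == sb[j - 1]:
                dp[i, j] = dp[i - 1, j - 1] + 1
            else:
                dp[i, j] = max(dp[i - 1, j], dp[i, j - 1])
    out: list[int] = []
    i, j = la, lb
    while i > 0 and j > 0:
        if sa[i - 1] == sb[j - 1]:
            out.append(sa[i - 1])
            i -= 1
            j -= 1
        elif dp[i - 1, j] >= dp[i, j - 1]:
            i -= 1
        else:
            j -= 1
    return PostureSequence(out[::-1])


def lcs_multi(seqs: list[PostureSequence]) -> PostureSequence:
    """Exact longest common subsequence of up to 6 short sequences.

    Runs the k-dimensional dynamic program over suffixes with memoization.
    When all k current symbols agree, taking the match is always optimal and
    is taken; otherwise the axes are advanced in fixed order, preferring the
    lowest axis among those achieving the maximum — a deterministic
    generalization of the pairwise tie-break.

    The k-dimensional table is exponential in k, so inputs are guarded:
    at most ``MAX_LCS_SEQUENCES`` sequences of length ``MAX_LCS_LENGTH``
    each, and a cap on the total state count.  Beyond the guards a
    ``ValueError`` advises pairwise approximation.
    """
    if not 1 <= len(seqs) <= MAX_LCS_SEQUENCES:
        raise ValueError(
            f"lcs_multi accepts 1..{MAX_LCS_SEQUENCES} sequences; "
            "fold longer collections pairwise with lcs_pair"
        )
    if len(seqs) == 1:
        return PostureSequence(list(seqs[0].symbols))
    syms = [s.symbols for s in seqs]
    lens = [len(s) for s in syms]
    if any(n > MAX_LCS_LENGTH for n in lens):
        raise ValueError(
            f"sequence length exceeds {MAX_LCS_LENGTH}; "
            "approximate by folding pairwise with lcs_pair"
        )
    states = 1
    for n in lens:
        states *= n + 1
    if states > _MAX_LCS_STATES:
        raise ValueError(
            "multi-sequence LCS table too large; "
            "approximate by folding pairwise with lcs_pair"
        )

    k = len(syms)
    memo: dict[tuple[int, ...], int] = {}
    sys.setrecursionlimit(max(sys.getrecursionlimit(), sum(lens) + 100))

    def length(idx: tuple[int, ...]) -> int:
        if any(idx[a] >= lens[a] for a in range(k)):
            return 0
        cached = memo.get(idx)
        if cached is not None:
            return cached
        first = syms[0][idx[0]]
        if all(syms[a][idx[a]] == first for a in range(1, k)):
            # matching all k heads is always optimal (exchange argument)
            val = 1 + length(tuple(i + 1 for i in idx))
        else:
            val = 0
            for a in range(k):
                nxt = list(idx)
                nxt[a] += 1
                val = max(val, length(tuple(nxt)))
        memo[idx] = val
        return val

    out: list[int] = []
    idx = tuple(0 for _ in range(k))
    while all(idx[a] < lens[a] for a in range(k)):
        first = syms[0][idx[0]]
        if all(syms[a][idx[a]] == first for a in range(1, k)):
            out.append(first)
            idx = tuple(i + 1 for i in idx)
            continue
        target = length(idx)
        for a in range(k):  # lowest axis achieving the optimum
            nxt = list(idx)
            nxt[a] += 1
            if length(tuple(nxt)) == target:
                idx = tuple(nxt)
                break
    return PostureSequence(out)


@dataclass
class TemplateEntry:
    label: str
    sequence: PostureSequence  # collapsed
    map: TrajectoryMap


@dataclass
class TemplateLibrary:
    """Exercise label -> template; plus the rejection threshold."""

    entries: dict[str, TemplateEntry] = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [-1, 1]")

    def add(self, entry: TemplateEntry) -> None:
        if entry.label in self.entries:
            raise ValueError(f"duplicate template label {entry.label!r}")
        self.entries[entry.label] = entry

    def to_json(self, path) -> None:
        obj = {
            "threshold": self.threshold,
            "entries": {
                e.label: {
                    "sequence": list(e.sequence.symbols),
                    "M": int(e.map.image.shape[0]),
                    "N": int(e.map.image.shape[1]),
                    "image": e.map.image.ravel().tolist(),
                    "appearance": {str(k): v for k, v in e.map.appearance.items()},
                }
                for e in self.entries.values()
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "TemplateLibrary":
        with open(path) as fh:
            obj = json.load(fh)
        lib = cls(threshold=obj["threshold"])
        for label, e in obj["entries"].items():
            img = np.array(e["image"], dtype=np.uint8).reshape(e["M"], e["N"])
            seq = PostureSequence(e["sequence"], collapsed=True)
            tmap = TrajectoryMap(
                image=img,
                appearance={int(k): v for k, v in e["appearance"].items()},
                sequence=list(seq.symbols),
            )
            lib.add(TemplateEntry(label=label, sequence=seq, map=tmap))
        return lib


def build_template(pmap: PostureMap, label: str, instances) -> TemplateEntry:
    """Distill one template from several instances of the same exercise.

    Each instance (a list of feature vectors) is encoded and collapsed; the
    multi-sequence LCS of the collapsed sequences becomes the template
    sequence, rendered as the template map.  An empty LCS means the
    instances share no structure and is an error.
    """
    instances = list(instances)
    if not instances:
        raise ValueError("need at least one instance")
    collapsed = [collapse_repetitions(encode(pmap, inst)) for inst in instances]
    if len(collapsed) <= MAX_LCS_SEQUENCES and all(
        len(c) <= MAX_LCS_LENGTH for c in collapsed
    ):
        template = lcs_multi(collapsed)
    else:  # too many/long instances: fold pairwise (order-dependent heuristic)
        template = collapsed[0]
        for c in collapsed[1:]:
            template = lcs_pair(template, c)
    if len(template) == 0:
        raise ValueError(
            f"instances of {label!r} share no common subsequence; "
            "check recording quality"
        )
    template = PostureSequence(template.symbols, collapsed=True)
    return TemplateEntry(
        label=label, sequence=template, map=render_trajectory_map(pmap, template)
    )


def similarity(p: TrajectoryMap, t: TrajectoryMap) -> float:
    """Normalized image correlation between two trajectory maps.

    Pearson-type correlation of the two images about their means; lies in
    [-1, 1].  A constant image has no defined correlation and raises.
    """
    a = np.asarray(p.image, dtype=float)
    b = np.asarray(t.image, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt((da**2).sum())
    nb = np.sqrt((db**2).sum())
    if na == 0.0 or nb == 0.0:
        raise ValueError("similarity undefined for a constant image")
    return float((da * db).sum() / (na * nb))


@dataclass
class ClassificationResult:
    label: str | None  # None on rejection
    score: float  # best similarity, also reported on rejection
    rejected: bool
    scores: dict[str, float] = field(default_factory=dict)


def classify(p: TrajectoryMap, lib: TemplateLibrary) -> ClassificationResult:
    """Best-correlation classification with threshold rejection.

    Scores every template; returns the top label (ties -> lexicographically
    smallest) when the best score reaches the library threshold, otherwise a
    rejection carrying the best score.
    """
    if not lib.entries:
        raise ValueError("template library is empty")
    scores = {
        label: similarity(p, entry.map) for label, entry in sorted(lib.entries.items())
    }
    best_label = max(sorted(scores), key=lambda k: scores[k])
    best = scores[best_label]
    if best < lib.threshold:
        return ClassificationResult(label=None, score=best, rejected=True, scores=scores)
    return ClassificationResult(label=best_label, score=best, rejected=False, scores=scores)
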