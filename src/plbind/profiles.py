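"""Sequence profiles and w x 21 sliding-window feature encoding.

A profile is an L x 20 matrix of position-specific log-odds scores, read
from a PSI-BLAST ASCII PSSM or computed from a multiple sequence alignment.
Each residue example is the w profile rows centred on it, flattened, with a
per-slot terminal-spacer flag marking window slots that fall outside the
sequence; the feature vector therefore has length w x 21.
"""

from __future__ import annotations

import dataclasses
import json
import re
from collections.abc import Iterable, Mapping, Sequence

import numpy as np

from .dataset import ResidueLabelSet

__all__ = [
    "AA_ORDER",
    "ProfileMatrix",
    "WindowVector",
    "LabeledDataset",
    "ProfileFormatError",
    "FeatureConsistencyError",
    "parse_psiblast_pssm",
    "profile_from_alignment",
    "window_encode",
    "vectorize_dataset",
    "save_features",
    "load_features",
]

# PSI-BLAST column order
AA_ORDER = "ARNDCQEGHILKMFPSTWVY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


class ProfileFormatError(ValueError):
    pass


class FeatureConsistencyError(ValueError):
    pass


@dataclasses.dataclass
class ProfileMatrix:
    seq_id: str
    scores: np.ndarray  # (L, 20) log-odds
    sequence: str | None = None
    column_order: str = AA_ORDER

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("profile scores must be an (L, 20) matrix")
        if not np.isfinite(self.scores).all():
            raise ValueError("profile scores must be finite")
        if self.sequence is not None and len(self.sequence) != self.scores.shape[0]:
            raise ValueError("sequence length does not match profile rows")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclasses.dataclass
class WindowVector:
    seq_id: str
    center: int  # 1-based
    w: int
    values: np.ndarray  # flat, length w * 21: per slot 20 scores + spacer flag

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.w * 21,):
            raise ValueError("window vector length must be w * 21")

    @property
    def spacers(self) -> np.ndarray:
        return self.values[20::21]


@dataclasses.dataclass
class LabeledDataset:
    """Feature matrix plus labels and (seq_id, position) provenance."""

    X: np.ndarray  # (n, w * 21)
    y: np.ndarray  # (n,) in {0, 1}
    meta: list[tuple[str, int]]
    w: int

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.meta):
            raise ValueError("X, y and meta must agree in length")
        if self.X.shape[1] != self.w * 21:
            raise ValueError("feature dimension must equal w * 21")


_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Z])\s+(-?\d)")


def parse_psiblast_pssm(text: str, seq_id: str = "", sequence: str | None = None) -> ProfileMatrix:
    """Parse the ``-out_ascii_pssm`` dialect; keeps the 20 log-odds columns.

    Rows carrying both log-odds and percentage blocks (40 numeric columns)
    are accepted; only the first 20 are used.  Residue letters are checked
    against ``sequence`` when given.
    """
    rows: list[list[float]] = []
    letters: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not _PSSM_ROW.match(line):
            continue
        tokens = line.split()
        numeric = tokens[2:]
        if len(numeric) < 20:
            raise ProfileFormatError(
                f"line {lineno}: expected >= 20 score columns, got {len(numeric)}"
            )
        idx = int(tokens[0])
        if idx != len(rows) + 1:
            raise ProfileFormatError(f"line {lineno}: non-contiguous position index {idx}")
        try:
            rows.append([float(v) for v in numeric[:20]])
        except ValueError as exc:
            raise ProfileFormatError(f"line {lineno}: {exc}") from None
        letters.append(tokens[1])
    if not rows:
        raise ProfileFormatError("no PSSM rows found in stream")
    observed = "".join(letters)
    if sequence is not None and observed != sequence:
        raise FeatureConsistencyError(
            f"{seq_id or '<pssm>'}: PSSM residues do not match the sequence"
        )
    return ProfileMatrix(seq_id=seq_id, scores=np.array(rows), sequence=sequence or observed)


def profile_from_alignment(
    msa: Sequence[tuple[str, str]] | Sequence,
    pseudocount: float = 1.0,
    seq_id: str | None = None,
) -> ProfileMatrix:
    """Log-odds profile from an aligned FASTA family.

    The first record is the master; profile rows correspond to its non-gap
    columns.  With uniform background bg = 1/20,

        score(a) = log2( (count(a) + pseudocount * bg) / ((N + pseudocount) * bg) )

    where N counts standard residues observed at the column.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    records: list[tuple[str, str]] = []
    for rec in msa:
        if isinstance(rec, tuple):
            records.append((rec[0], str(rec[1]).upper()))
        else:  # Bio.SeqRecord
            records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ProfileFormatError("empty alignment")
    width = len(records[0][1])
    if any(len(s) != width for _, s in records):
        raise ProfileFormatError("ragged alignment: rows differ in length")

    master_id, master = records[0]
    bg = 1.0 / 20.0
    rows = []
    master_seq = []
    for col in range(width):
        if master[col] in "-.":
            continue
        master_seq.append(master[col])
        counts = np.zeros(20)
        for _, s in records:
            j = _AA_INDEX.get(s[col])
            if j is not None:
                counts[j] += 1
        n = counts.sum()
        rows.append(np.log2((counts + pseudocount * bg) / ((n + pseudocount) * bg)))
    return ProfileMatrix(
        seq_id=seq_id if seq_id is not None else master_id,
        scores=np.array(rows),
        sequence="".join(master_seq),
    )


def window_encode(
    profile: ProfileMatrix, center: int, w: int, scale: float = 1.0
) -> WindowVector:
    """Encode one residue as the w profile rows around it plus spacer flags.

    Slots outside [1, L] get 20 zero scores and spacer flag 1; in-sequence
    slots carry ``scale`` times their profile row and spacer flag 0.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window size must be odd and >= 1, got {w}")
    length = len(profile)
    if not 1 <= center <= length:
        raise ValueError(f"center {center} outside [1, {length}]")
    half = (w - 1) // 2
    values = np.zeros(w * 21)
    for slot, pos in enumerate(range(center - half, center + half + 1)):
        base = slot * 21
        if 1 <= pos <= length:
            values[base : base + 20] = profile.scores[pos - 1] * scale
        else:
            values[base + 20] = 1.0
    return WindowVector(seq_id=profile.seq_id, center=center, w=w, values=values)


def vectorize_dataset(
    labelsets: Iterable[ResidueLabelSet],
    profiles: Mapping[str, ProfileMatrix],
    w: int,
    scale: float = 0.1,
) -> LabeledDataset:
    """One (window vector, label) example per labeled position.

    Examples are ordered by (seq_id, position); profile log-odds are scaled
    by ``scale`` (default 1/10) to keep RBF kernel inputs bounded.
    """
    items: list[tuple[str, int, int]] = []
    for ls in labelsets:
        items.extend((ls.seq_id, pos, 1) for pos in ls.positives)
        items.extend((ls.seq_id, pos, 0) for pos in ls.negatives)
    items.sort(key=lambda t: (t[0], t[1]))

    X = np.zeros((len(items), w * 21))
    y = np.zeros(len(items), dtype=int)
    meta = []
    for i, (sid, pos, label) in enumerate(items):
        prof = profiles.get(sid)
        if prof is None:
            raise FeatureConsistencyError(f"no profile for sequence {sid}")
        if pos > len(prof):
            raise FeatureConsistencyError(f"{sid}: position {pos} beyond profile length")
        X[i] = window_encode(prof, pos, w, scale=scale).values
        y[i] = label
        meta.append((sid, pos))
    return LabeledDataset(X=X, y=y, meta=meta, w=w)


def save_features(data: LabeledDataset, path: str) -> None:
    """NPZ container with a JSON sidecar describing provenance."""
    np.savez(path, X=data.X, y=data.y)
    sidecar = {
        "w": data.w,
        "column_order": AA_ORDER,
        "examples": [{"seq_id": s, "position": p, "label": int(l)} for (s, p), l in zip(data.meta, data.y)],
    }
    with open(str(path).removesuffix(".npz") + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_features(path: str) -> LabeledDataset:
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as npz:
        X, y = npz["X"], npz["y"]
    with open(str(path).removesuffix(".npz") + ".json") as fh:
        sidecar = json.load(fh)
    meta = [(e["seq_id"], e["position"]) for e in sidecar["examples"]]
    return LabeledDataset(X=X, y=y, meta=meta, w=sidecar["w"])
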