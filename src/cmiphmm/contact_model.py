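"""Residue-residue contact-matrix prediction.

Each residue is described by its 20-dim Fisher score vector plus a
sliding window of amino-acid property values: 11 window slots x 17
properties = 187 features.  A residue pair concatenates both residues'
blocks into a (20 + 187) x 2 = 414-dim vector, min-max normalized to
[0, 1] on the training fold, and an RBF-kernel SVM classifies the pair
as contact / non-contact.  Applied to every match-column pair of two
decoded sequences this yields the predicted contact matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .alphabet import AA_INDEX
from .iphmm import Decoding
from .msa_io import AAIndexTable, ContactMatrix

DEFAULT_WINDOW = 11


# ---------------------------------------------------------------------------
# Per-residue features
# ---------------------------------------------------------------------------

def aaindex_pad_values(aaindex: AAIndexTable,
                       sequences: list[str] | None) -> np.ndarray:
    """Per-property padding value for window slots outside a sequence.

    The mean of each property over all residues of the training
    sequences; with no sequences given, the mean over the 20 residue
    types (both are neutral after min-max scaling).
    """
    mat = aaindex.matrix()  # (P, 20)
    if not sequences:
        return mat.mean(axis=1)
    counts = np.zeros(20)
    for seq in sequences:
        for ch in seq:
            counts[AA_INDEX[ch]] += 1
    if counts.sum() == 0:
        return mat.mean(axis=1)
    freqs = counts / counts.sum()
    return mat @ freqs


def residue_window_features(seq: str, aaindex: AAIndexTable, pos: int,
                            window: int = DEFAULT_WINDOW,
                            pad: np.ndarray | None = None) -> np.ndarray:
    """Windowed property vector for the residue at 0-based ``pos``.

    Slot order is offset-major (offset -w..+w), property-minor (table
    order), giving ``window * len(aaindex)`` values; out-of-sequence
    slots are filled with ``pad`` (default: residue-type property means).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if not 0 <= pos < len(seq):
        raise ValueError(f"pos {pos} outside sequence of length {len(seq)}")
    mat = aaindex.matrix()
    n_props = mat.shape[0]
    if pad is None:
        pad = mat.mean(axis=1)
    half = window // 2
    out = np.empty(window * n_props)
    for slot, off in enumerate(range(-half, half + 1)):
        p = pos + off
        if 0 <= p < len(seq):
            vals = mat[:, AA_INDEX[seq[p]]]
        else:
            vals = pad
        out[slot * n_props:(slot + 1) * n_props] = vals
    return out


@dataclass
class ResidueFeatures:
    """Fisher block (20) + windowed property block for one residue."""

    fisher: np.ndarray
    aaidx_window: np.ndarray

    def vector(self) -> np.ndarray:
        return np.concatenate([self.fisher, self.aaidx_window])


def build_pair_vector(fa: ResidueFeatures, fb: ResidueFeatures) -> np.ndarray:
    """Residue-pair vector: [A.fisher, A.window, B.fisher, B.window].

    Asymmetric by convention — domain A always occupies the first half.
    """
    return np.concatenate([fa.vector(), fb.vector()])


# ---------------------------------------------------------------------------
# [0, 1] normalization
# ---------------------------------------------------------------------------

@dataclass
class MinMaxNormalizer:
    """Per-feature min-max scaling fitted on training vectors.

    Constant features map to 0; test-time values are clamped to [0, 1].
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, vectors: np.ndarray) -> "MinMaxNormalizer":
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[0] == 0:
            raise ValueError("normalizer needs a non-empty 2-D training set")
        return cls(mins=vectors.min(axis=0), maxs=vectors.max(axis=0))

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        scaled = (vectors - self.mins) / safe
        scaled = np.where(span > 0, scaled, 0.0)
        return np.clip(scaled, 0.0, 1.0)


# ---------------------------------------------------------------------------
# The SVM contact classifier
# ---------------------------------------------------------------------------

@dataclass
class ContactModel:
    """RBF-SVM over normalized residue-pair vectors."""

    svm: SVC
    normalizer: MinMaxNormalizer
    gamma: float | str
    C: float
    n_features: int

    def decision_values(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(vectors)
        if vectors.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features}-dim pair vectors, got "
                f"{vectors.shape[1]}")
        return self.svm.decision_function(self.normalizer.apply(vectors))


def train_contact_svm(vectors: np.ndarray, labels: np.ndarray,
                      gamma: float | str = "scale", C: float = 1.0) -> ContactModel:
    """Fit the RBF-SVM contact classifier on labeled pair vectors.

    ``gamma`` defaults to the SVM library's default kernel width
    ``"scale"`` (1 / (n_features * Var(X))); both classes must be
    present.
    """
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if vectors.ndim != 2 or len(vectors) != len(labels):
        raise ValueError("vectors and labels must align")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(
            f"training set contains a single class ({classes.tolist()}); "
            "both contact and non-contact examples are required")
    n_features = vectors.shape[1]
    if gamma is None:
        gamma = "scale"
    norm = MinMaxNormalizer.fit(vectors)
    svm = SVC(kernel="rbf", gamma=gamma, C=C)
    svm.fit(norm.apply(vectors), labels)
    return ContactModel(svm=svm, normalizer=norm, gamma=gamma, C=C,
                        n_features=n_features)


# ---------------------------------------------------------------------------
# Matrix-level prediction
# ---------------------------------------------------------------------------

def residue_features_for_columns(dec: Decoding, fisher: np.ndarray,
                                 aaindex: AAIndexTable,
                                 column_residues: np.ndarray,
                                 window: int = DEFAULT_WINDOW,
                                 pad: np.ndarray | None = None
                                 ) -> dict[int, ResidueFeatures]:
    """Feature blocks for every occupied match column of one sequence.

    ``column_residues`` maps each 0-based match column to the 0-based
    residue position representing it (-1 for deleted columns), either
    from the known alignment row (training) or from posterior assignment
    (prediction).
    """
    out: dict[int, ResidueFeatures] = {}
    for j, pos in enumerate(column_residues):
        if pos < 0:
            continue
        out[j] = ResidueFeatures(
            fisher=fisher[pos],
            aaidx_window=residue_window_features(dec.seq, aaindex, int(pos),
                                                 window=window, pad=pad))
    return out


def predict_contact_matrix(model: ContactModel,
                           feats_a: dict[int, ResidueFeatures],
                           feats_b: dict[int, ResidueFeatures],
                           n_match_a: int, n_match_b: int,
                           family_id: str = "", pair_id: str = ""
                           ) -> tuple[ContactMatrix, ContactMatrix]:
    """Predict the full match-coordinate contact matrix for one pair.

    Returns ``(binary, score)`` matrices; cells whose row or column is a
    deleted match state are 0 in the binary matrix and carry the minimum
    decision value in the score matrix.
    """
    scores = np.zeros((n_match_a, n_match_b))
    cells = [(ja, jb) for ja in feats_a for jb in feats_b]
    if cells:
        vecs = np.array([build_pair_vector(feats_a[ja], feats_b[jb])
                         for ja, jb in cells])
        dv = model.decision_values(vecs)
        floor = dv.min()
        scores[:] = min(floor, 0.0)
        for (ja, jb), v in zip(cells, dv):
            scores[ja, jb] = v
    binary = (scores > 0).astype(float)
    mask = np.zeros_like(scores, dtype=bool)
    for ja in feats_a:
        for jb in feats_b:
            mask[ja, jb] = True
    binary[~mask] = 0.0
    cm_bin = ContactMatrix(family_id=family_id, pair_id=pair_id,
                           cells=binary, kind="predicted_binary")
    cm_score = ContactMatrix(family_id=family_id, pair_id=pair_id,
                             cells=scores, kind="predicted_score")
    return cm_bin, cm_score
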