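"""The integrated site classifier (CM-ipHMM) and its ablations.

Per residue, the feature vector is the residue's row (domain A) or
column (domain B) of the contact matrix, followed by the residue's
ipHMM interface posterior in the last slot.  A per-family, per-domain
L2-penalized logistic regression maps this vector to the probability
that the residue is an interface residue:

    Pr(Y=1 | x) = 1 / (1 + exp(-(b0 + b . x)))

Variants:
``cm_iphmm``        predicted contact matrix + ipHMM posterior (the method)
``cm_only``         predicted contact matrix alone (drops the last slot)
``ground_truth_cm`` true contact matrix + ipHMM posterior (upper bound)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .msa_io import ContactMatrix

VARIANTS = ("cm_iphmm", "cm_only", "ground_truth_cm")
METHODS = ("iphmm",) + VARIANTS


@dataclass
class SiteFeatureVector:
    """Features for one residue of one domain.

    ``features`` has length partner-n_match (+1 unless the variant is
    ``cm_only``); the ipHMM score, when present, is the final slot.
    """

    seq_id: str
    match_index: int            # 0-based match column of the residue
    features: np.ndarray
    label: int | None = None    # 1 = interacting (training only)


def build_site_features(cm: ContactMatrix, site_scores: np.ndarray,
                        domain_role: str, variant: str,
                        columns: list[int], seq_id: str = "",
                        labels: dict[int, int] | None = None
                        ) -> list[SiteFeatureVector]:
    """Per-residue vectors for the given match columns of one sequence.

    Domain A residues take matrix rows, domain B residues matrix
    columns; ``site_scores`` is the per-match-column ipHMM interface
    posterior of this sequence's own domain.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if domain_role not in ("A", "B"):
        raise ValueError(f"domain_role must be 'A' or 'B', got {domain_role!r}")
    n_own = cm.n_rows if domain_role == "A" else cm.n_cols
    if len(site_scores) != n_own:
        raise ValueError(
            f"site_scores length {len(site_scores)} != domain match count "
            f"{n_own}")
    out = []
    for j in columns:
        if not 0 <= j < n_own:
            raise ValueError(f"match column {j} outside 0..{n_own - 1}")
        slice_ = cm.cells[j, :] if domain_role == "A" else cm.cells[:, j]
        if variant == "cm_only":
            feats = np.asarray(slice_, dtype=float)
        else:
            feats = np.append(np.asarray(slice_, dtype=float),
                              float(site_scores[j]))
        out.append(SiteFeatureVector(
            seq_id=seq_id, match_index=j, features=feats,
            label=None if labels is None else labels.get(j)))
    return out


def oversample_positives(data: list[SiteFeatureVector],
                         seed: int) -> list[SiteFeatureVector]:
    """Resample interacting residues with replacement until class counts
    match, then shuffle; deterministic given ``seed``."""
    pos = [d for d in data if d.label == 1]
    neg = [d for d in data if d.label == 0]
    if not pos or not neg:
        missing = "positive (interacting)" if not pos else "negative (non-interacting)"
        raise ValueError(f"cannot oversample: no {missing} examples present")
    rng = np.random.default_rng(seed)
    out = list(pos) + list(neg)
    if len(pos) < len(neg):
        extra = rng.integers(0, len(pos), size=len(neg) - len(pos))
        out += [pos[i] for i in extra]
    rng.shuffle(out)
    return out


@dataclass
class LogisticSiteModel:
    """Per-(family, domain, variant) logistic-regression site classifier."""

    clf: LogisticRegression
    domain_role: str
    variant: str
    n_features: int
    C: float = 1.0
    converged: bool = True

    @property
    def coefficients(self) -> np.ndarray:
        return self.clf.coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.clf.intercept_[0])


def train_site_model(data: list[SiteFeatureVector], domain_role: str,
                     variant: str, C: float = 1.0,
                     max_iter: int = 1000, tol: float = 1e-6
                     ) -> LogisticSiteModel:
    """Fit the L2-penalized logistic site classifier on (oversampled)
    labeled residues.  Non-convergence is flagged, not fatal."""
    X = np.array([d.features for d in data])
    y = np.array([d.label for d in data], dtype=int)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("empty training set")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training data must contain both classes")
    # L2 penalty with strength C (sklearn's default regularizer)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=tol)
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X, y)
    if not np.all(np.isfinite(clf.coef_)):
        raise ValueError("logistic fit produced non-finite coefficients")
    return LogisticSiteModel(clf=clf, domain_role=domain_role,
                             variant=variant, n_features=X.shape[1], C=C,
                             converged=converged)


def sigmoid_probability(model: LogisticSiteModel,
                        vectors: np.ndarray) -> np.ndarray:
    """Direct evaluation of the logistic model on raw feature vectors."""
    from scipy.special import expit
    vectors = np.atleast_2d(vectors)
    return expit(model.intercept + vectors @ model.coefficients)


def predict_sites_integrated(model: LogisticSiteModel,
                             vectors: list[SiteFeatureVector] | np.ndarray,
                             threshold: float = 0.5
                             ) -> tuple[np.ndarray, np.ndarray]:
    """(probability, binary call) per residue; probability > threshold
    means interacting, a tie goes to non-interacting."""
    if isinstance(vectors, list):
        X = np.array([v.features for v in vectors])
    else:
        X = np.atleast_2d(vectors)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} != model dimension "
            f"{model.n_features}")
    prob = sigmoid_probability(model, X)
    return prob, prob > threshold
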