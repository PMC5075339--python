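"""Cross-validated evaluation of the site-prediction pipeline.

The protocol is family-wise leave-one-out: for each sequence pair of a
DDI family, both domain ipHMMs, the contact SVM and the per-domain
logistic site models are trained on the remaining pairs only, and all
method variants are scored on the held-out pair.  Metrics (accuracy,
precision, recall, F1, MCC) are computed per sequence from confusion
counts over that sequence's non-deleted match columns, then
macro-averaged across all sequences of all families.  Undefined ratios
(zero denominators) are reported as NaN null markers and excluded from
averages with an exclusion count — never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contact_model import (aaindex_pad_values, build_pair_vector,
                            predict_contact_matrix,
                            residue_features_for_columns, train_contact_svm)
from .integrator import (METHODS, VARIANTS, SiteFeatureVector,
                         build_site_features, oversample_positives,
                         predict_sites_integrated, train_site_model)
from .iphmm import build_iphmm, fisher_scores, forward_backward, predict_sites
from .msa_io import AAIndexTable, ContactMatrix, LabeledAlignment, SiteLabel


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """Site-level confusion counts; positives are interacting residues."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class Metrics:
    """Standard binary metrics; ``None`` marks an undefined ratio."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    mcc: float | None


def compute_metrics(cc: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall, F1 and MCC from confusion counts.

    Any metric whose denominator is zero is returned as ``None``.
    """
    if cc.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, tn, fp, fn = cc.TP, cc.TN, cc.FP, cc.FN
    accuracy = (tp + tn) / cc.total
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return Metrics(accuracy=accuracy, precision=precision, recall=recall,
                   f1=f1, mcc=mcc)


METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "mcc")


def confusion_from_frame(df: pd.DataFrame) -> ConfusionCounts:
    """Brute-force recount of a prediction frame's confusion counts."""
    t = df["label_true"].to_numpy(dtype=int)
    p = df["label_pred"].to_numpy(dtype=int)
    return ConfusionCounts(TP=int(np.sum((t == 1) & (p == 1))),
                           TN=int(np.sum((t == 0) & (p == 0))),
                           FP=int(np.sum((t == 0) & (p == 1))),
                           FN=int(np.sum((t == 1) & (p == 0))))


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Classical two-sided paired t-test on per-unit metric values.

    Zero-variance differences are reported as degenerate (infinite t for
    a nonzero mean difference) rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0)
        return PairedTestResult(t=math.copysign(math.inf, mean), df=n - 1,
                                p=0.0, mean_diff=mean, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(res.statistic), df=n - 1,
                            p=float(res.pvalue), mean_diff=mean)


# ---------------------------------------------------------------------------
# Family container and pipeline parameters
# ---------------------------------------------------------------------------

@dataclass
class FamilyData:
    """One DDI family: two labeled alignments, ground-truth contact
    matrices per pair, and the pairing of alignment rows."""

    aln_A: LabeledAlignment
    aln_B: LabeledAlignment
    contact_matrices: dict[str, ContactMatrix]
    pairs: list[tuple[str, str, str]]   # (pair_id, seq_id_A, seq_id_B)

    @property
    def family_id(self) -> str:
        return self.aln_A.family_id


def as_family_data(family) -> FamilyData:
    """Accept a FamilyData or anything with the same attributes (such as
    a :class:`cmiphmm.synthetic.SyntheticFamily`)."""
    if isinstance(family, FamilyData):
        return family
    return FamilyData(aln_A=family.aln_A, aln_B=family.aln_B,
                      contact_matrices=family.contact_matrices,
                      pairs=family.pairs)


@dataclass
class PipelineParams:
    """Stage parameters; defaults are the method's stated values."""

    pseudocount: float = 1.0
    window: int = 11
    svm_gamma: float | str = "scale"  # RBF width; "scale" = library default
    C_svm: float = 1.0
    C_logreg: float = 1.0
    threshold: float = 0.5
    cm_feature_kind: str = "predicted_binary"   # or "predicted_score"
    site_score_binary: bool = False   # feed binary ipHMM call, not p_int
    oversample_contacts: bool = True  # balance contact classes (see docs)
    cv: str = "loocv"                 # or "tenfold"
    seed: int = 0


class _ConstantContactModel:
    """Fallback when a training fold has a single contact class: every
    cell receives the same decision value (sign of the lone class)."""

    def __init__(self, value: float, n_features: int):
        self.value = value
        self.n_features = n_features

    def decision_values(self, vectors: np.ndarray) -> np.ndarray:
        return np.full(np.atleast_2d(vectors).shape[0], self.value)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _fold_indices(n: int, cv: str, seed: int) -> list[list[int]]:
    if cv == "loocv":
        return [[k] for k in range(n)]
    if cv == "tenfold":
        k = 10
        if n < k:
            raise ValueError(
                f"tenfold cross-validation needs >= {k} pairs, family has {n}")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        return [sorted(order[i::k].tolist()) for i in range(k)]
    raise ValueError(f"unknown cv protocol {cv!r}")


def _fold_seed(seed: int, fold: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence([seed, fold, salt]).generate_state(1)[0]
               % (2**31 - 1))


def _alignment_column_map(aln: LabeledAlignment, seq_id: str) -> np.ndarray:
    """Per 0-based match column: the 0-based residue position of this
    row, or -1 where the row has a gap."""
    out = np.full(aln.n_match, -1, dtype=int)
    for j, c in enumerate(aln.match_columns):
        pos = aln.residue_position(seq_id, c)
        if pos is not None:
            out[j] = pos
    return out


def _label_map(aln: LabeledAlignment, seq_id: str) -> dict[int, int]:
    """0-based match column -> binary interacting label (residue cells)."""
    out = {}
    for j, c in enumerate(aln.match_columns):
        lab = aln.site_labels[(seq_id, c)]
        if lab is not SiteLabel.GAP:
            out[j] = int(lab is SiteLabel.INTERACTING)
    return out


@dataclass
class CrossValResult:
    """All per-residue predictions of one family's cross-validation."""

    family_id: str
    predictions: pd.DataFrame
    contact_predictions: dict[str, tuple[ContactMatrix, ContactMatrix]]
    notes: list[str] = field(default_factory=list)


def crossval_family(family, aaindex: AAIndexTable,
                    params: PipelineParams | None = None,
                    methods: Iterable[str] = METHODS) -> CrossValResult:
    """Run the full pipeline under the configured CV protocol.

    Per fold: both domain ipHMMs are rebuilt without the held-out
    pair(s); the contact SVM is trained on the remaining pairs' residue
    pairs; per-domain logistic site models are trained on the remaining
    pairs' residues (positives oversampled); every requested method is
    evaluated on the held-out pair(s) only.  No held-out information
    enters any training stage.
    """
    fam = as_family_data(family)
    params = params or PipelineParams()
    methods = list(methods)
    bad = [m for m in methods if m not in METHODS]
    if bad:
        raise ValueError(f"unknown methods {bad}; choose from {METHODS}")
    n = len(fam.pairs)
    if n < 2:
        raise ValueError(f"family {fam.family_id} has {n} pair(s); "
                         "cross-validation needs at least 2")
    folds = _fold_indices(n, params.cv, params.seed)
    rows: list[dict] = []
    notes: list[str] = []

    # ---- stage 1: per fold, rebuild ipHMMs and the contact SVM without
    # the held-out pair(s); reserve the held-out pair's ipHMM site
    # posteriors and predicted contact matrix for the site stage.
    reserved: dict[str, dict] = {}
    fold_of_pair: dict[str, int] = {}
    for fold_idx, test_set in enumerate(folds):
        test_ids = {fam.pairs[k][0] for k in test_set}
        train_pairs = [p for p in fam.pairs if p[0] not in test_ids]
        test_pairs = [p for p in fam.pairs if p[0] in test_ids]
        aln_a = fam.aln_A.subset([sa for _, sa, _ in train_pairs])
        aln_b = fam.aln_B.subset([sb for _, _, sb in train_pairs])
        model_a = build_iphmm(aln_a, pseudocount=params.pseudocount)
        model_b = build_iphmm(aln_b, pseudocount=params.pseudocount)
        pad_a = aaindex_pad_values(
            aaindex, [fam.aln_A.degapped(sa) for _, sa, _ in train_pairs])
        pad_b = aaindex_pad_values(
            aaindex, [fam.aln_B.degapped(sb) for _, _, sb in train_pairs])

        def decode(role: str, sid: str, is_test: bool) -> dict:
            model, aln, pad = ((model_a, fam.aln_A, pad_a) if role == "A"
                               else (model_b, fam.aln_B, pad_b))
            dec = forward_backward(model, aln.degapped(sid), seq_id=sid)
            fp = fisher_scores(model, dec)
            # training rows use their known alignment column map;
            # held-out rows are mapped by posterior assignment
            colmap = (dec.column_residues() if is_test
                      else _alignment_column_map(aln, sid))
            feats = residue_features_for_columns(
                dec, fp.scores, aaindex, colmap,
                window=params.window, pad=pad)
            return {"seq_id": sid, "feats": feats,
                    "sites": predict_sites(dec, threshold=params.threshold),
                    "labels": _label_map(aln, sid)}

        train_info = {pid: {"A": decode("A", sa, False),
                            "B": decode("B", sb, False)}
                      for pid, sa, sb in train_pairs}

        vec_list, lab_list = [], []
        for pid, _, _ in train_pairs:
            ea, eb = train_info[pid]["A"], train_info[pid]["B"]
            gt = fam.contact_matrices[pid]
            for ja, fa in ea["feats"].items():
                for jb, fb in eb["feats"].items():
                    vec_list.append(build_pair_vector(fa, fb))
                    lab_list.append(int(gt.cells[ja, jb]))
        vecs = np.asarray(vec_list)
        labs = np.asarray(lab_list)
        if params.oversample_contacts and 0 < labs.sum() < len(labs) / 2:
            rng = np.random.default_rng(_fold_seed(params.seed, fold_idx, 99))
            pos = np.flatnonzero(labs == 1)
            extra = rng.choice(pos, size=int((labs == 0).sum() - pos.size))
            vecs = np.vstack([vecs, vecs[extra]])
            labs = np.concatenate([labs, labs[extra]])
        try:
            cmodel = train_contact_svm(vecs, labs,
                                       gamma=params.svm_gamma, C=params.C_svm)
        except ValueError as exc:
            only = int(labs[0]) if len(labs) else 0
            cmodel = _ConstantContactModel(1.0 if only else -1.0,
                                           vecs.shape[1] if len(vecs) else 0)
            notes.append(f"fold {fold_idx}: contact SVM fallback ({exc})")

        for pid, sa, sb in test_pairs:
            ea, eb = decode("A", sa, True), decode("B", sb, True)
            cm_bin, cm_score = predict_contact_matrix(
                cmodel, ea["feats"], eb["feats"],
                fam.aln_A.n_match, fam.aln_B.n_match,
                family_id=fam.family_id, pair_id=pid)
            reserved[pid] = {"A": ea, "B": eb,
                             "cm": (cm_bin, cm_score)}
            fold_of_pair[pid] = fold_idx

    # ---- stage 2: per fold, train the per-domain site models on the
    # remaining pairs' reserved features and test on the held-out pair.
    # Using each training pair's own reserved (out-of-fold) matrix keeps
    # the feature distribution identical between training and testing.
    score_idx = 0 if params.cm_feature_kind == "predicted_binary" else 1

    def site_vectors(pair_id: str, role: str, variant: str,
                     training: bool) -> list[SiteFeatureVector]:
        entry = reserved[pair_id][role]
        if variant == "ground_truth_cm":
            cm = fam.contact_matrices[pair_id]
        else:
            cm = reserved[pair_id]["cm"][score_idx]
        sites = entry["sites"]
        scores = (sites.calls.astype(float) if params.site_score_binary
                  else sites.p_int)
        columns = sorted(entry["labels"])
        return build_site_features(
            cm, scores, role, variant, columns, seq_id=entry["seq_id"],
            labels=entry["labels"] if training else None)

    variants = [m for m in methods if m in VARIANTS]
    for fold_idx, test_set in enumerate(folds):
        test_ids = {fam.pairs[k][0] for k in test_set}
        train_ids = [p[0] for p in fam.pairs if p[0] not in test_ids]
        for role in ("A", "B"):
            for variant in variants:
                train_vecs: list[SiteFeatureVector] = []
                for pid in train_ids:
                    train_vecs += site_vectors(pid, role, variant, True)
                salt = VARIANTS.index(variant) * 2 + (role == "B")
                fold_seed = _fold_seed(params.seed, fold_idx, salt)
                try:
                    balanced = oversample_positives(train_vecs, fold_seed)
                    smodel = train_site_model(balanced, role, variant,
                                              C=params.C_logreg)
                except ValueError as exc:
                    notes.append(f"fold {fold_idx} {role}/{variant}: "
                                 f"constant fallback ({exc})")
                    smodel = None
                for pid in sorted(test_ids):
                    tv = site_vectors(pid, role, variant, False)
                    if not tv:
                        continue
                    if smodel is None:
                        only = train_vecs[0].label if train_vecs else 0
                        prob = np.full(len(tv), float(only))
                        call = prob > params.threshold
                    else:
                        prob, call = predict_sites_integrated(
                            smodel, tv, threshold=params.threshold)
                    entry = reserved[pid][role]
                    for v, pr, cl in zip(tv, prob, call):
                        rows.append(dict(
                            method=variant, family_id=fam.family_id,
                            pair_id=pid, domain_role=role,
                            seq_id=entry["seq_id"],
                            match_index=v.match_index,
                            label_true=entry["labels"][v.match_index],
                            label_pred=int(cl), score=float(pr)))

    if "iphmm" in methods:
        for pid, _, _ in fam.pairs:
            for role in ("A", "B"):
                entry = reserved[pid][role]
                sites = entry["sites"]
                for j, lab in sorted(entry["labels"].items()):
                    rows.append(dict(
                        method="iphmm", family_id=fam.family_id,
                        pair_id=pid, domain_role=role,
                        seq_id=entry["seq_id"], match_index=j,
                        label_true=lab, label_pred=int(sites.calls[j]),
                        score=float(sites.p_int[j])))

    preds = pd.DataFrame(rows)
    contact_out = {pid: reserved[pid]["cm"] for pid in reserved}
    return CrossValResult(family_id=fam.family_id, predictions=preds,
                          contact_predictions=contact_out, notes=notes)


def loocv_family(family, aaindex: AAIndexTable,
                 params: PipelineParams | None = None,
                 methods: Iterable[str] = METHODS) -> CrossValResult:
    """Leave-one-out protocol (the default); see :func:`crossval_family`."""
    params = params or PipelineParams()
    if params.cv != "loocv":
        params = PipelineParams(**{**params.__dict__, "cv": "loocv"})
    return crossval_family(family, aaindex, params, methods)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-sequence, per-family and overall macro-averaged metrics."""

    per_sequence: pd.DataFrame
    per_family: pd.DataFrame
    overall: pd.DataFrame
    excluded: dict[str, dict[str, int]]
    paired_tests: dict[str, PairedTestResult] = field(default_factory=dict)


def per_sequence_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """One metric row per (method, sequence); NaN marks undefined."""
    recs = []
    keys = ["method", "family_id", "pair_id", "domain_role", "seq_id"]
    for key, grp in predictions.groupby(keys, sort=True):
        cc = confusion_from_frame(grp)
        m = compute_metrics(cc)
        rec = dict(zip(keys, key))
        rec["n_residues"] = cc.total
        for name in METRIC_NAMES:
            v = getattr(m, name)
            rec[name] = np.nan if v is None else v
        recs.append(rec)
    return pd.DataFrame(recs)


def aggregate_report(per_family_predictions: Iterable[pd.DataFrame],
                     test_pairs: Sequence[tuple[str, str]] = (
                         ("cm_iphmm", "iphmm"), ("cm_iphmm", "cm_only")),
                     ) -> MetricsReport:
    """Macro-average per-sequence metrics across families and run the
    paired t-tests between the named method pairs (paired by sequence,
    on MCC; sequences where either value is undefined are dropped)."""
    frames = list(per_family_predictions)
    if not frames:
        raise ValueError("no prediction frames to aggregate")
    preds = pd.concat(frames, ignore_index=True)
    per_seq = per_sequence_metrics(preds)

    excluded: dict[str, dict[str, int]] = {}
    for method, grp in per_seq.groupby("method"):
        excluded[method] = {name: int(grp[name].isna().sum())
                            for name in METRIC_NAMES}
    per_family = (per_seq.groupby(["method", "family_id"])[list(METRIC_NAMES)]
                  .mean().reset_index())
    overall = per_seq.groupby("method")[list(METRIC_NAMES)].mean().reset_index()

    unit = ["family_id", "pair_id", "domain_role", "seq_id"]
    tests: dict[str, PairedTestResult] = {}
    for ma, mb in test_pairs:
        a = per_seq[per_seq.method == ma].set_index(unit)["mcc"]
        b = per_seq[per_seq.method == mb].set_index(unit)["mcc"]
        joined = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
        if len(joined) >= 2:
            tests[f"{ma}_vs_{mb}"] = paired_t_test(joined["a"], joined["b"])
    return MetricsReport(per_sequence=per_seq, per_family=per_family,
                         overall=overall, excluded=excluded,
                         paired_tests=tests)
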