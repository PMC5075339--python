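"""The interaction-profile HMM (ipHMM).

A profile HMM in which every match column ``j`` is split into a
non-interacting match state ``Mni(j)`` and an interacting match state
``Mi(j)``.  Connectivity otherwise follows the classic profile-HMM
(HMMER-style) architecture: Begin, per-column insert ``I(j)`` and
(silent) delete ``D(j)`` states, and End.  Decoding a sequence with
forward-backward therefore yields, per match column, the posterior
probability that the aligned residue is an interface residue.

All probability arithmetic is done in log space; silent states (Begin,
deletes, End) are handled by in-level topological propagation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA, is_gap, validate_residue
from .msa_io import LabeledAlignment, SiteLabel

_NEG_INF = -np.inf

SERIAL_FORMAT = "cmiphmm-iphmm"
SERIAL_VERSION = 1


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------

class StateSpace:
    """Integer ids and allowed arcs for an ipHMM with ``L`` match columns.

    Layout: ``B`` = 0, ``I(0)`` = 1, then per column ``j`` (1-based) the
    block ``Mni(j), Mi(j), I(j), D(j)``, and ``End`` last.
    """

    def __init__(self, L: int):
        if L < 1:
            raise ValueError("model needs at least one match column")
        self.L = L
        self.B = 0
        self.END = 2 + 4 * L
        self.n_states = self.END + 1

    def mni(self, j: int) -> int:
        return 2 + 4 * (j - 1)

    def mi(self, j: int) -> int:
        return 3 + 4 * (j - 1)

    def ins(self, j: int) -> int:
        return 1 if j == 0 else 4 + 4 * (j - 1)

    def dele(self, j: int) -> int:
        return 5 + 4 * (j - 1)

    def name(self, s: int) -> str:
        if s == self.B:
            return "B"
        if s == self.END:
            return "End"
        if s == 1:
            return "I0"
        j, off = divmod(s - 2, 4)
        return ("Mni", "Mi", "I", "D")[off] + str(j + 1)

    def state_id(self, name: str) -> int:
        if name == "B":
            return self.B
        if name == "End":
            return self.END
        kind = name.rstrip("0123456789")
        j = int(name[len(kind):])
        return {"Mni": self.mni, "Mi": self.mi, "I": self.ins,
                "D": self.dele}[kind](j)

    @property
    def emitting(self) -> np.ndarray:
        mask = np.zeros(self.n_states, dtype=bool)
        mask[1] = True
        for j in range(1, self.L + 1):
            mask[[self.mni(j), self.mi(j), self.ins(j)]] = True
        return mask

    def silent_topo(self) -> list[int]:
        """Silent states in forward topological order (D chain, then End)."""
        return [self.dele(j) for j in range(1, self.L + 1)] + [self.END]

    def allowed_arcs(self) -> list[tuple[int, int]]:
        L = self.L
        arcs: list[tuple[int, int]] = []
        arcs += [(self.B, self.mni(1)), (self.B, self.mi(1)),
                 (self.B, self.dele(1)), (self.B, self.ins(0))]
        for j in range(0, L + 1):
            i = self.ins(j)
            arcs.append((i, i))
            if j < L:
                arcs += [(i, self.mni(j + 1)), (i, self.mi(j + 1)),
                         (i, self.dele(j + 1))]
            else:
                arcs.append((i, self.END))
        for j in range(1, L + 1):
            for m in (self.mni(j), self.mi(j)):
                arcs.append((m, self.ins(j)))
                if j < L:
                    arcs += [(m, self.mni(j + 1)), (m, self.mi(j + 1)),
                             (m, self.dele(j + 1))]
                else:
                    arcs.append((m, self.END))
            d = self.dele(j)
            if j < L:
                arcs += [(d, self.dele(j + 1)), (d, self.mni(j + 1)),
                         (d, self.mi(j + 1))]
            else:
                arcs.append((d, self.END))
        return arcs


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

@dataclass
class IpHMM:
    """Parameterized interaction-profile HMM.

    ``T`` is the dense (S, S) transition matrix over the state space of
    :class:`StateSpace`; ``E`` the (S, 20) emission matrix with zero rows
    for silent states.  Outgoing-transition rows and emission rows of
    reachable states sum to one.
    """

    n_match: int
    T: np.ndarray
    E: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.space = StateSpace(self.n_match)
        self.T = np.asarray(self.T, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        S = self.space.n_states
        if self.T.shape != (S, S) or self.E.shape != (S, N_AA):
            raise ValueError("transition/emission matrices have wrong shape")
        allowed = np.zeros((S, S), dtype=bool)
        for a, b in self.space.allowed_arcs():
            allowed[a, b] = True
        if np.any(self.T[~allowed] != 0.0):
            raise ValueError("transition probability on a disallowed arc")
        row = self.T.sum(axis=1)
        ok = np.isclose(row, 1.0, atol=1e-9) | np.isclose(row, 0.0, atol=1e-9)
        if not ok.all():
            raise ValueError("outgoing transition rows must sum to 1 (or be "
                             "all-zero for unused states)")
        emit = self.space.emitting
        erow = self.E.sum(axis=1)
        if not np.all(np.isclose(erow[emit], 1.0, atol=1e-9)
                      | np.isclose(erow[emit], 0.0, atol=1e-9)):
            raise ValueError("emission rows must sum to 1")
        if np.any(self.E[~emit] != 0.0):
            raise ValueError("silent states cannot emit")
        with np.errstate(divide="ignore"):
            self._logT = np.log(self.T)
            self._logE = np.log(np.where(emit[:, None], self.E, 0.0))
            self._logE[~emit] = _NEG_INF

    # -- convenience accessors ----------------------------------------------

    def emission(self, state_name: str) -> np.ndarray:
        return self.E[self.space.state_id(state_name)]

    def transition(self, src: str, dst: str) -> float:
        return float(self.T[self.space.state_id(src),
                            self.space.state_id(dst)])

    @classmethod
    def from_tables(cls, match_ni: np.ndarray, match_i: np.ndarray,
                    insert: np.ndarray,
                    transitions: dict[str, dict[str, float]],
                    pseudocount: float = 1.0) -> "IpHMM":
        """Build from per-column emission tables and a named-arc dict.

        ``match_ni``/``match_i`` are (L, 20), ``insert`` is (L+1, 20);
        ``transitions`` maps source state name to {dest name: prob}.
        """
        L = np.asarray(match_ni).shape[0]
        sp = StateSpace(L)
        S = sp.n_states
        T = np.zeros((S, S))
        E = np.zeros((S, N_AA))
        for j in range(1, L + 1):
            E[sp.mni(j)] = match_ni[j - 1]
            E[sp.mi(j)] = match_i[j - 1]
        for j in range(0, L + 1):
            E[sp.ins(j)] = insert[j]
        for src, dests in transitions.items():
            for dst, p in dests.items():
                T[sp.state_id(src), sp.state_id(dst)] = p
        return cls(n_match=L, T=T, E=E, pseudocount=pseudocount)

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        sp = self.space
        arcs = [[sp.name(a), sp.name(b), self.T[a, b]]
                for a, b in sp.allowed_arcs() if self.T[a, b] > 0]
        emit = {}
        for s in np.flatnonzero(sp.emitting):
            emit[sp.name(int(s))] = self.E[int(s)].tolist()
        doc = {"format": SERIAL_FORMAT, "version": SERIAL_VERSION,
               "n_match": self.n_match, "pseudocount": self.pseudocount,
               "alphabet": AMINO_ACIDS, "transitions": arcs,
               "emissions": emit}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "IpHMM":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != SERIAL_FORMAT:
            raise ValueError(f"{path}: not an ipHMM model file")
        sp = StateSpace(int(doc["n_match"]))
        T = np.zeros((sp.n_states, sp.n_states))
        E = np.zeros((sp.n_states, N_AA))
        for src, dst, p in doc["transitions"]:
            T[sp.state_id(src), sp.state_id(dst)] = p
        for name, vec in doc["emissions"].items():
            E[sp.state_id(name)] = vec
        return cls(n_match=sp.L, T=T, E=E,
                   pseudocount=float(doc["pseudocount"]))


# ---------------------------------------------------------------------------
# Model construction from a labeled alignment
# ---------------------------------------------------------------------------

def implied_state_path(aln: LabeledAlignment, seq_id: str) -> list[int]:
    """The state path a row implies: match flavor from its label, delete
    from gaps at match columns, inserts from residues at insert columns."""
    sp = StateSpace(aln.n_match)
    match_set = {c: j + 1 for j, c in enumerate(aln.match_columns)}
    seq = aln.aligned(seq_id)
    path = [sp.B]
    j_cur = 0
    for c, ch in enumerate(seq):
        if c in match_set:
            j_cur = match_set[c]
            if is_gap(ch):
                path.append(sp.dele(j_cur))
            else:
                lab = aln.site_labels[(seq_id, c)]
                path.append(sp.mi(j_cur) if lab is SiteLabel.INTERACTING
                            else sp.mni(j_cur))
        elif not is_gap(ch):
            path.append(sp.ins(j_cur))
    path.append(sp.END)
    return path


def build_iphmm(aln: LabeledAlignment, pseudocount: float = 1.0) -> IpHMM:
    """Maximum-likelihood ipHMM from a labeled alignment with add-``k``
    pseudocounts (default add-one) on every emission cell and allowed arc.

    Emissions of ``Mi(j)`` come from residues labeled interacting in match
    column ``j``, ``Mni(j)`` from those labeled non-interacting, inserts
    from insert-column residues between consecutive match columns.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if aln.n_match == 0:
        raise ValueError("alignment has no match columns")
    sp = StateSpace(aln.n_match)
    S = sp.n_states
    e_counts = np.zeros((S, N_AA))
    t_counts = np.zeros((S, S))
    match_set = {c: j + 1 for j, c in enumerate(aln.match_columns)}
    for seq_id, seq in aln.rows:
        path = implied_state_path(aln, seq_id)
        for a, b in zip(path, path[1:]):
            t_counts[a, b] += 1
        j_cur = 0
        for c, ch in enumerate(seq):
            if is_gap(ch):
                if c in match_set:
                    j_cur = match_set[c]
                continue
            aa = AA_INDEX[ch]
            if c in match_set:
                j_cur = match_set[c]
                lab = aln.site_labels[(seq_id, c)]
                s = sp.mi(j_cur) if lab is SiteLabel.INTERACTING else sp.mni(j_cur)
            else:
                s = sp.ins(j_cur)
            e_counts[s, aa] += 1

    T = np.zeros((S, S))
    for a, b in sp.allowed_arcs():
        T[a, b] = t_counts[a, b] + pseudocount
    row = T.sum(axis=1)
    T[row > 0] /= row[row > 0, None]

    E = np.zeros((S, N_AA))
    emit = sp.emitting
    E[emit] = e_counts[emit] + pseudocount
    E[emit] /= E[emit].sum(axis=1, keepdims=True)
    return IpHMM(n_match=sp.L, T=T, E=E, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

@dataclass
class Decoding:
    """Forward-backward result for one sequence under one ipHMM.

    ``gamma[i, s]`` is the posterior that residue ``i`` (0-based position
    in the ungapped sequence) was emitted by state ``s``; rows sum to one
    over emitting states.
    """

    seq_id: str
    seq: str
    model: IpHMM
    log_likelihood: float
    gamma: np.ndarray

    def match_mass(self) -> np.ndarray:
        """(n, L) posterior mass of residue i on match column j (both
        flavors combined)."""
        sp = self.model.space
        n = len(self.seq)
        out = np.empty((n, sp.L))
        for j in range(1, sp.L + 1):
            out[:, j - 1] = (self.gamma[:, sp.mi(j)]
                             + self.gamma[:, sp.mni(j)])
        return out

    def best_match_column(self) -> tuple[np.ndarray, np.ndarray]:
        """Per residue: (argmax match column, its posterior mass).

        Columns are 0-based; residues with (numerically) zero match mass
        keep an argmax of -1.
        """
        mm = self.match_mass()
        best = mm.argmax(axis=1)
        mass = mm[np.arange(len(best)), best]
        best = np.where(mass > 1e-12, best, -1)
        return best, mass

    def column_residues(self) -> np.ndarray:
        """Per match column (0-based): the residue position assigned to
        it by posterior argmax, or -1 if no residue maps there (the
        sequence deletes the column)."""
        best, mass = self.best_match_column()
        out = np.full(self.model.n_match, -1, dtype=int)
        for j in range(self.model.n_match):
            cand = np.flatnonzero(best == j)
            if cand.size:
                out[j] = cand[np.argmax(mass[cand])]
        return out

    def site_probability(self) -> np.ndarray:
        """Per match column, posterior mass on ``Mi`` normalized over
        ``{Mi, Mni}``; 0 for columns with no match mass."""
        sp = self.model.space
        p = np.zeros(sp.L)
        for j in range(1, sp.L + 1):
            mi = self.gamma[:, sp.mi(j)].sum()
            mni = self.gamma[:, sp.mni(j)].sum()
            if mi + mni > 1e-12:
                p[j - 1] = mi / (mi + mni)
        return p


def _encode(seq: str) -> np.ndarray:
    x = np.empty(len(seq), dtype=int)
    for i, ch in enumerate(seq):
        validate_residue(ch, position=i)
        x[i] = AA_INDEX[ch]
    return x


def forward_backward(model: IpHMM, seq: str, seq_id: str = "") -> Decoding:
    """Log-space forward-backward with silent-state propagation.

    Returns posteriors over emitting states per residue and the total
    forward log-likelihood (which equals the backward total within
    numerical tolerance).
    """
    if not seq:
        raise ValueError("sequence is empty")
    x = _encode(seq)
    n = len(x)
    sp = model.space
    S = sp.n_states
    logT, logE = model._logT, model._logE
    silent_fwd = sp.silent_topo()

    f = np.full((n + 1, S), _NEG_INF)
    f[0, sp.B] = 0.0
    for s in silent_fwd:
        col = f[0] + logT[:, s]
        f[0, s] = logsumexp(col) if np.any(np.isfinite(col)) else _NEG_INF
    for i in range(1, n + 1):
        prev = f[i - 1]
        with np.errstate(invalid="ignore"):
            reach = logsumexp(prev[:, None] + logT, axis=0)
        f[i] = reach + logE[:, x[i - 1]]
        for s in silent_fwd:
            col = f[i] + logT[:, s]
            f[i, s] = logsumexp(col) if np.any(np.isfinite(col)) else _NEG_INF
    loglik = f[n, sp.END]
    if not np.isfinite(loglik):
        raise ValueError("sequence has zero likelihood under the model")

    silent_rev = list(reversed(silent_fwd))
    b = np.full((n + 1, S), _NEG_INF)
    c = np.full(S, _NEG_INF)  # combined successor value at current level
    b[n, sp.END] = 0.0
    c[sp.END] = 0.0
    for s in silent_rev[1:]:  # D_L .. D_1 at level n
        row = logT[s] + c
        b[n, s] = logsumexp(row) if np.any(np.isfinite(row)) else _NEG_INF
        c[s] = b[n, s]
    with np.errstate(invalid="ignore"):
        b[n] = np.where(sp.emitting,
                        logsumexp(logT + c[None, :], axis=1), b[n])
    for i in range(n - 1, -1, -1):
        c = np.where(sp.emitting, logE[:, x[i]] + b[i + 1], _NEG_INF)
        for s in silent_rev:
            row = logT[s] + c
            b[i, s] = logsumexp(row) if np.any(np.isfinite(row)) else _NEG_INF
            c[s] = b[i, s]
        with np.errstate(invalid="ignore"):
            emit_b = logsumexp(logT + c[None, :], axis=1)
        b[i] = np.where(sp.emitting, emit_b, b[i])

    # B is silent and precedes every other state; close the recursion at
    # level 0 (its successors are level-1 emitting states and D(1)).
    row = logT[sp.B] + np.where(sp.emitting, logE[:, x[0]] + b[1], c)
    b[0, sp.B] = logsumexp(row)
    if not np.isclose(b[0, sp.B], loglik, rtol=1e-8, atol=1e-8):
        raise AssertionError(
            f"forward/backward totals disagree: {loglik} vs {b[0, sp.B]}")

    gamma = np.zeros((n, S))
    emit = sp.emitting
    for i in range(1, n + 1):
        g = f[i, emit] + b[i, emit] - loglik
        gamma[i - 1, emit] = np.exp(g)
    return Decoding(seq_id=seq_id, seq=seq, model=model,
                    log_likelihood=float(loglik), gamma=gamma)


# ---------------------------------------------------------------------------
# Site calls and Fisher scores
# ---------------------------------------------------------------------------

@dataclass
class SiteCalls:
    """Binary interaction-site calls per match column."""

    p_int: np.ndarray        # (L,) posterior interface probability
    calls: np.ndarray        # (L,) bool; True = interacting
    occupied: np.ndarray     # (L,) bool; False = column deleted


def predict_sites(dec: Decoding, threshold: float = 0.5) -> SiteCalls:
    """Call a match column interacting iff its interface posterior
    exceeds ``threshold`` (ties go to the majority class,
    non-interacting); deleted columns are non-interacting with p 0."""
    p = dec.site_probability()
    occupied = dec.column_residues() >= 0
    p = np.where(occupied, p, 0.0)
    calls = p > threshold
    return SiteCalls(p_int=p, calls=calls, occupied=occupied)


@dataclass
class FisherProfile:
    """Per-residue 20-vectors of log-likelihood gradients w.r.t. the
    emission parameters of the residue's best-supported match column.

    Each vector sums to zero (constrained-gradient identity); residues
    with no posterior match mass (pure inserts) carry zero vectors and
    are flagged in ``insert_flags``.
    """

    seq_id: str
    scores: np.ndarray       # (n, 20)
    insert_flags: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def fisher_scores(model: IpHMM, dec: Decoding) -> FisherProfile:
    """Fisher scores: how the sequence's log-likelihood responds to
    mutating each residue, evaluated against the emission distributions
    of its best posterior match column.

    ``F_i(a) = sum over flavors m of gamma(i, m(j*)) * (1[x_i=a] - e_m(j*)(a))``
    """
    sp = model.space
    x = _encode(dec.seq)
    n = len(x)
    best, _ = dec.best_match_column()
    scores = np.zeros((n, N_AA))
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        j = int(best[i])
        if j < 0:
            flags[i] = True
            continue
        onehot = np.zeros(N_AA)
        onehot[x[i]] = 1.0
        for state in (sp.mi(j + 1), sp.mni(j + 1)):
            g = dec.gamma[i, state]
            if g > 0:
                scores[i] += g * (onehot - model.E[state])
    return FisherProfile(seq_id=dec.seq_id, scores=scores, insert_flags=flags)
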