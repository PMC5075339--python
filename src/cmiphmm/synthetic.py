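"""Synthetic domain-domain interaction (DDI) families with known truth.

A family consists of two domain alignments (A and B), per-residue
interaction labels, and one binary contact matrix per sequence pair.
The generative model is deliberately matched to the assumptions of the
prediction pipeline so that benchmark results read as correctness
checks:

* every match column has a strongly conserved consensus residue with a
  small substitution rate (profile columns are conserved by definition);
* a fixed subset of columns per domain are *interface* columns, joined
  by a family-level bipartite contact pattern in which every interface
  column participates (one shared interface topology per family);
* interface columns split into *core* (hot-spot) columns, engaged in
  every family member, and *rim* columns whose engagement varies: per
  pair, each rim column is independently *active* with probability
  1 - inactivation_rate, while core columns are always active.  Active
  columns emit from the column's interface distribution (its own, more
  conserved consensus), inactive ones from the background distribution.
  The contact pattern is assortative (core contacts core, rim contacts
  rim) and a contact is realized exactly when both endpoint columns are
  active, so the matrices differ across pairs while staying inside the
  interface block;
* a residue is labeled interacting iff it has at least one contact in
  its own pair's matrix — the label a structure-derived dataset would
  assign.  The partner side of that condition is invisible to a
  single-domain model, which is precisely the information channel the
  contact-matrix feedback exploits.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA
from .msa_io import ContactMatrix, LabeledAlignment, SiteLabel

DEFAULT_LENGTH_BOUND = 150


@dataclass
class FamilySpec:
    """Parameters of one synthetic DDI family.

    Defaults give a mid-sized family (14 members, as in the 10-20 member
    range of curated DDI datasets) whose summed domain length stays well
    under the 150-residue processing bound.
    """

    seed: int
    family_id: str = "fam"
    n_pairs: int = 14
    len_A: int = 20
    len_B: int = 24
    frac_interface: float = 0.25
    emission_sharpness: float = 2.0
    contact_density: float = 0.2
    indel_rate: float = 0.03
    label_noise: float = 0.0
    inactivation_rate: float = 0.35
    core_fraction: float = 0.5
    substitution_rate: float = 0.04

    def __post_init__(self) -> None:
        if not 0 < self.frac_interface < 1:
            raise ValueError("frac_interface must be in (0, 1)")
        if self.len_A + self.len_B >= DEFAULT_LENGTH_BOUND:
            raise ValueError(
                f"len_A + len_B must be < {DEFAULT_LENGTH_BOUND}")
        for name in ("contact_density", "indel_rate", "label_noise",
                     "inactivation_rate", "core_fraction",
                     "substitution_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.emission_sharpness <= 0:
            raise ValueError("emission_sharpness must be positive")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    def n_interface(self, length: int) -> int:
        k = int(round(self.frac_interface * length))
        if k < 1:
            raise ValueError(
                f"frac_interface {self.frac_interface} yields zero "
                f"interface columns for length {length}")
        return min(k, length - 1)


@dataclass
class DomainTruth:
    """Generating parameters of one domain."""

    interface_columns: np.ndarray     # 0-based match columns, sorted
    core_columns: frozenset[int]      # always-engaged interface columns
    background: np.ndarray            # (L, 20) emission distributions
    interface_active: dict[int, np.ndarray]  # col -> 20-vector
    insert: np.ndarray                # (20,) insert emission


@dataclass
class SyntheticFamily:
    """One generated family: alignments, truth parameters, matrices."""

    spec: FamilySpec
    aln_A: LabeledAlignment
    aln_B: LabeledAlignment
    truth_A: DomainTruth
    truth_B: DomainTruth
    contact_pattern: set[tuple[int, int]]
    contact_matrices: dict[str, ContactMatrix]
    pairs: list[tuple[str, str, str]]   # (pair_id, seq_id_A, seq_id_B)

    @property
    def family_id(self) -> str:
        return self.spec.family_id

    @property
    def pair_ids(self) -> list[str]:
        return [p for p, _, _ in self.pairs]


def _column_distribution(rng: np.random.Generator, eps: float,
                         exclude: int | None = None) -> np.ndarray:
    """Consensus residue with substitution mass ``eps`` spread over
    three alternate residues."""
    choices = [a for a in range(N_AA) if a != exclude]
    consensus = int(rng.choice(choices))
    others = [a for a in range(N_AA) if a != consensus]
    alts = rng.choice(others, size=3, replace=False)
    w = rng.dirichlet(np.ones(3))
    dist = np.zeros(N_AA)
    dist[consensus] = 1.0 - eps
    dist[alts] += eps * w
    return dist


def _sample_domain_truth(spec: FamilySpec, length: int,
                         rng: np.random.Generator) -> DomainTruth:
    n_int = spec.n_interface(length)
    iface = np.sort(rng.choice(length, size=n_int, replace=False))
    eps = spec.substitution_rate
    background = np.array([_column_distribution(rng, eps)
                           for _ in range(length)])
    # engaged-state emissions: a distinct (and, for sharpness > 1, more
    # conserved) consensus, blended toward background as sharpness -> 0
    # so that emission_sharpness interpolates from "interface invisible
    # in sequence" to "fully distinct interface consensus" (reached at
    # sharpness 2, the default).
    lam = min(1.0, spec.emission_sharpness / 2.0)
    active = {}
    for col in iface:
        bg_consensus = int(np.argmax(background[col]))
        raw = _column_distribution(
            rng, eps / max(spec.emission_sharpness, 1.0),
            exclude=bg_consensus)
        active[int(col)] = lam * raw + (1.0 - lam) * background[col]
    insert = rng.dirichlet(np.ones(N_AA))
    n_core = int(round(spec.core_fraction * n_int))
    core = frozenset(int(c) for c in
                     rng.choice(iface, size=n_core, replace=False))
    return DomainTruth(interface_columns=iface, core_columns=core,
                       background=background, interface_active=active,
                       insert=insert)


def _sample_contact_pattern(truth_a: DomainTruth, truth_b: DomainTruth,
                            density: float,
                            rng: np.random.Generator) -> set[tuple[int, int]]:
    """Assortative bipartite pattern over interface columns: core
    columns contact core columns of the partner domain and rim columns
    contact rim columns; every interface column participates in at
    least one contact (crossing class only when a side has no columns
    of the matching class)."""
    ia, ib = truth_a.interface_columns, truth_b.interface_columns
    ca, cb = truth_a.core_columns, truth_b.core_columns

    def block(left, right):
        return {(int(a), int(b)) for a in left for b in right
                if rng.random() < density}

    core_a = [c for c in ia if int(c) in ca]
    rim_a = [c for c in ia if int(c) not in ca]
    core_b = [c for c in ib if int(c) in cb]
    rim_b = [c for c in ib if int(c) not in cb]
    pattern = block(core_a, core_b) | block(rim_a, rim_b)

    def fixup(cols, partners_same, partners_any, is_row):
        for c in cols:
            c = int(c)
            hit = any((x == c) if is_row else (y == c) for x, y in pattern)
            if not hit:
                pool = partners_same if len(partners_same) else partners_any
                p = int(rng.choice(pool))
                pattern.add((c, p) if is_row else (p, c))

    fixup(core_a, core_b, ib, True)
    fixup(rim_a, rim_b, ib, True)
    fixup(core_b, core_a, ia, False)
    fixup(rim_b, rim_a, ia, False)
    return pattern


def _emit_row(spec: FamilySpec, truth: DomainTruth, active: dict[int, bool],
              rng: np.random.Generator
              ) -> tuple[list[str], list[list[str]]]:
    """One sequence: per-match-column residue (or gap) and per-slot
    insertions (slot j sits after match column j; slot 0 before 1)."""
    L = truth.background.shape[0]
    residues: list[str] = []
    for col in range(L):
        if rng.random() < spec.indel_rate:
            residues.append("-")
            continue
        if active.get(col, False):
            dist = truth.interface_active[col]
        else:
            dist = truth.background[col]
        residues.append(AMINO_ACIDS[int(rng.choice(N_AA, p=dist))])
    inserts: list[list[str]] = []
    for slot in range(L + 1):
        ins: list[str] = []
        while rng.random() < spec.indel_rate:
            ins.append(AMINO_ACIDS[int(rng.choice(N_AA, p=truth.insert))])
        inserts.append(ins)
    return residues, inserts


def _assemble(family_id: str, domain_role: str, length: int,
              rows: list[tuple[str, list[str], list[list[str]],
                               dict[int, bool]]]) -> LabeledAlignment:
    """Merge per-row residues/insertions into one gapped alignment."""
    slot_width = [max(len(r[2][s]) for r in rows) for s in range(length + 1)]
    aligned_rows: list[tuple[str, str]] = []
    match_columns: list[int] = []
    site_labels: dict[tuple[str, int], SiteLabel] = {}
    first = True
    for seq_id, residues, inserts, labels in rows:
        chars: list[str] = []
        for col in range(length):
            ins = inserts[col]
            chars += ins + ["-"] * (slot_width[col] - len(ins))
            if first:
                match_columns.append(len(chars))
            chars.append(residues[col])
        ins = inserts[length]
        chars += ins + ["-"] * (slot_width[length] - len(ins))
        aligned_rows.append((seq_id, "".join(chars)))
        first = False
        for col in range(length):
            c = match_columns[col]
            if residues[col] == "-":
                site_labels[(seq_id, c)] = SiteLabel.GAP
            else:
                site_labels[(seq_id, c)] = (
                    SiteLabel.INTERACTING if labels.get(col, False)
                    else SiteLabel.NON_INTERACTING)
    return LabeledAlignment(family_id=family_id, domain_role=domain_role,
                            rows=aligned_rows, match_columns=match_columns,
                            site_labels=site_labels)


def sample_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate one family deterministically from its spec."""
    rng = np.random.default_rng(spec.seed)
    truth_a = _sample_domain_truth(spec, spec.len_A, rng)
    truth_b = _sample_domain_truth(spec, spec.len_B, rng)
    pattern = _sample_contact_pattern(truth_a, truth_b,
                                      spec.contact_density, rng)

    rows_a, rows_b = [], []
    matrices: dict[str, ContactMatrix] = {}
    pairs: list[tuple[str, str, str]] = []
    for k in range(spec.n_pairs):
        pair_id = f"p{k + 1:02d}"
        sid_a, sid_b = f"{pair_id}A", f"{pair_id}B"
        act_a = {int(c): (rng.random() >= spec.inactivation_rate
                          or int(c) in truth_a.core_columns)
                 for c in truth_a.interface_columns}
        act_b = {int(c): (rng.random() >= spec.inactivation_rate
                          or int(c) in truth_b.core_columns)
                 for c in truth_b.interface_columns}
        res_a, ins_a = _emit_row(spec, truth_a, act_a, rng)
        res_b, ins_b = _emit_row(spec, truth_b, act_b, rng)
        cells = np.zeros((spec.len_A, spec.len_B))
        for a, b in pattern:
            if (act_a[a] and act_b[b]
                    and res_a[a] != "-" and res_b[b] != "-"):
                cells[a, b] = 1.0
        matrices[pair_id] = ContactMatrix(
            family_id=spec.family_id, pair_id=pair_id, cells=cells,
            kind="ground_truth")
        lab_a = {a: bool(cells[a, :].any()) for a in range(spec.len_A)}
        lab_b = {b: bool(cells[:, b].any()) for b in range(spec.len_B)}
        if spec.label_noise > 0:
            for col in range(spec.len_A):
                if res_a[col] != "-" and rng.random() < spec.label_noise:
                    lab_a[col] = not lab_a[col]
            for col in range(spec.len_B):
                if res_b[col] != "-" and rng.random() < spec.label_noise:
                    lab_b[col] = not lab_b[col]
        rows_a.append((sid_a, res_a, ins_a, lab_a))
        rows_b.append((sid_b, res_b, ins_b, lab_b))
        pairs.append((pair_id, sid_a, sid_b))

    aln_a = _assemble(spec.family_id, "A", spec.len_A, rows_a)
    aln_b = _assemble(spec.family_id, "B", spec.len_B, rows_b)
    return SyntheticFamily(spec=spec, aln_A=aln_a, aln_B=aln_b,
                           truth_A=truth_a, truth_B=truth_b,
                           contact_pattern=pattern,
                           contact_matrices=matrices, pairs=pairs)


def benchmark_suite(n_families: int, base_spec: FamilySpec | None = None,
                    seed: int = 0) -> list[SyntheticFamily]:
    """A reproducible multi-family benchmark with jittered parameters.

    The base spec uses compact domains (12 + 14 match columns, 10
    members) so a full leave-one-out sweep over the suite stays fast;
    family sizes and interface fractions are jittered around it.
    """
    if n_families < 2:
        raise ValueError("benchmark needs at least 2 families")
    if base_spec is None:
        base_spec = FamilySpec(seed=0, n_pairs=12, len_A=12, len_B=14)
    rng = np.random.default_rng(seed)
    families = []
    for i in range(n_families):
        len_a = int(base_spec.len_A + rng.integers(-2, 3))
        len_b = int(base_spec.len_B + rng.integers(-2, 3))
        frac = float(np.clip(base_spec.frac_interface
                             + rng.uniform(-0.05, 0.05), 0.1, 0.9))
        fam_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base_spec, seed=fam_seed,
                       family_id=f"fam{i + 1:02d}", len_A=len_a,
                       len_B=len_b, frac_interface=frac)
        families.append(sample_family(spec))
    return families
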