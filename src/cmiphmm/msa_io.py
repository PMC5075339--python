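"""Readers and writers for every external format the pipeline touches.

Formats
-------
* Labeled multiple sequence alignments: Stockholm with a ``#=GC RF``
  reference line marking match columns (``x`` = match, ``.`` = insert)
  and a ``#=GR <seq> PPI`` markup line carrying per-residue interaction
  labels (``i`` = interacting, ``n`` = non-interacting, ``.`` = gap or
  insert column); an annotated-FASTA dialect is accepted as well.
* Amino-acid property scales in AAindex1 flat-file layout.
* Binary / real residue-residue contact matrices as TSV with a
  ``#kind=`` header comment.
* Per-residue prediction reports as TSV.

Match-state indices and residue positions are 1-based in all files and
0-based everywhere inside the package; the conversion happens here and
only here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import (AAINDEX_ROW1, AAINDEX_ROW2, AMINO_ACIDS,
                       is_gap, validate_residue)


class FormatError(ValueError):
    """A file does not parse under its declared dialect."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


class SiteLabel(str, enum.Enum):
    INTERACTING = "interacting"
    NON_INTERACTING = "non_interacting"
    GAP = "gap"


#: The default amino-acid property accessions (alpha-CH chemical shift,
#: hydrophobicity, helix/turn propensities, flexibility, mutability,
#: side-chain geometry and stability scales), in feature order.
DEFAULT_AAINDEX_ACCESSIONS: tuple[str, ...] = (
    "ANDN920101", "ARGP820101", "BEGF750101", "BUNA790103", "BHAR880101",
    "BURA740102", "GEOR030101", "CHOP780204", "CHOP780215", "JOND920102",
    "KHAG800101", "FAUJ880104", "PALJ810107", "RACS820114", "WERD780103",
    "YUTK870102", "CHAM830102",
)

#: Default cap on summed domain lengths; bounds the contact-matrix size.
DEFAULT_LENGTH_BOUND = 150

_LABEL_CHARS = {"i": SiteLabel.INTERACTING, "n": SiteLabel.NON_INTERACTING,
                ".": SiteLabel.GAP}
_LABEL_TO_CHAR = {v: k for k, v in _LABEL_CHARS.items()}


# ---------------------------------------------------------------------------
# Labeled alignments
# ---------------------------------------------------------------------------

@dataclass
class LabeledAlignment:
    """A domain-family alignment with per-residue interaction labels.

    Parameters
    ----------
    family_id : str
        Identifier of the domain-domain interaction family.
    domain_role : str
        ``"A"`` or ``"B"`` — which side of the interaction this domain is.
    rows : list of (seq_id, aligned_seq)
        Gapped sequences over the 20-letter alphabet plus ``-``.
    match_columns : list of int
        0-based alignment columns designated as match states, strictly
        increasing.  Every other column is an insert column.
    site_labels : dict
        ``(seq_id, column) -> SiteLabel`` for every match column; residue
        cells carry ``interacting``/``non_interacting``, gap cells ``gap``.
    """

    family_id: str
    domain_role: str
    rows: list[tuple[str, str]]
    match_columns: list[int]
    site_labels: dict[tuple[str, int], SiteLabel]

    def __post_init__(self) -> None:
        if self.domain_role not in ("A", "B"):
            raise ValidationError(
                f"domain_role must be 'A' or 'B', got {self.domain_role!r}")
        if not self.rows:
            raise ValidationError("alignment has no rows")
        width = len(self.rows[0][1])
        for seq_id, seq in self.rows:
            if len(seq) != width:
                raise FormatError(
                    f"ragged alignment: row {seq_id!r} has length "
                    f"{len(seq)}, expected {width}")
            for pos, ch in enumerate(seq):
                if not is_gap(ch):
                    try:
                        validate_residue(ch, position=pos,
                                         context=f"row {seq_id!r}")
                    except ValueError as exc:
                        raise FormatError(str(exc)) from None
        mc = list(self.match_columns)
        if any(b <= a for a, b in zip(mc, mc[1:])):
            raise ValidationError("match_columns must be strictly increasing")
        if mc and (mc[0] < 0 or mc[-1] >= width):
            raise ValidationError("match_columns out of alignment range")
        expected = set()
        for seq_id, seq in self.rows:
            for c in mc:
                expected.add((seq_id, c))
        if set(self.site_labels) != expected:
            raise ValidationError(
                "site_labels must be defined exactly on (row, match column)")
        for (seq_id, c), lab in self.site_labels.items():
            seq = dict(self.rows)[seq_id]
            if is_gap(seq[c]) != (lab is SiteLabel.GAP):
                raise ValidationError(
                    f"label {lab.value!r} inconsistent with cell "
                    f"({seq_id!r}, column {c + 1})")

    # -- convenience views ---------------------------------------------------

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_match(self) -> int:
        return len(self.match_columns)

    @property
    def seq_ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def aligned(self, seq_id: str) -> str:
        return dict(self.rows)[seq_id]

    def degapped(self, seq_id: str) -> str:
        return "".join(ch for ch in self.aligned(seq_id) if not is_gap(ch))

    def residue_position(self, seq_id: str, column: int) -> int | None:
        """0-based position in the degapped sequence of the residue at
        ``column``, or ``None`` if the row has a gap there."""
        seq = self.aligned(seq_id)
        if is_gap(seq[column]):
            return None
        return sum(1 for ch in seq[:column] if not is_gap(ch))

    def match_label_vector(self, seq_id: str) -> list[SiteLabel]:
        """Labels in match-state order (length ``n_match``) for one row."""
        return [self.site_labels[(seq_id, c)] for c in self.match_columns]

    def subset(self, keep_ids: Sequence[str]) -> "LabeledAlignment":
        """Alignment restricted to ``keep_ids`` (training-fold view)."""
        keep = set(keep_ids)
        rows = [(sid, s) for sid, s in self.rows if sid in keep]
        labels = {k: v for k, v in self.site_labels.items() if k[0] in keep}
        return LabeledAlignment(self.family_id, self.domain_role, rows,
                                list(self.match_columns), labels)


def _labels_to_string(aln_width: int, match_columns: Sequence[int],
                      seq: str, labels: dict[int, SiteLabel]) -> str:
    chars = ["."] * aln_width
    for c in match_columns:
        lab = labels[c]
        chars[c] = _LABEL_TO_CHAR[lab]
    return "".join(chars)


def _assemble_alignment(family_id: str, domain_role: str,
                        rows: list[tuple[str, str]], rf: str,
                        label_strings: dict[str, str],
                        path: str) -> LabeledAlignment:
    if not rows:
        raise FormatError(f"{path}: no sequences found")
    width = len(rows[0][1])
    if len(rf) != width:
        raise FormatError(
            f"{path}: reference line length {len(rf)} != alignment "
            f"width {width}")
    match_columns = [i for i, ch in enumerate(rf) if ch == "x"]
    site_labels: dict[tuple[str, int], SiteLabel] = {}
    for seq_id, seq in rows:
        if seq_id not in label_strings:
            raise FormatError(f"{path}: missing label line for {seq_id!r}")
        lab = label_strings[seq_id]
        if len(lab) != width:
            raise FormatError(
                f"{path}: label string for {seq_id!r} has length "
                f"{len(lab)} != alignment width {width}")
        for c in match_columns:
            ch = lab[c]
            if ch not in _LABEL_CHARS:
                raise FormatError(
                    f"{path}: invalid label character {ch!r} for "
                    f"{seq_id!r} at column {c + 1}")
            value = _LABEL_CHARS[ch]
            if is_gap(seq[c]):
                value = SiteLabel.GAP
            elif value is SiteLabel.GAP:
                raise FormatError(
                    f"{path}: residue cell ({seq_id!r}, column {c + 1}) "
                    "carries gap label '.'")
            site_labels[(seq_id, c)] = value
    return LabeledAlignment(family_id, domain_role, rows, match_columns,
                            site_labels)


def read_labeled_alignment(path: str | Path,
                           dialect: str = "stockholm_markup") -> LabeledAlignment:
    """Read a labeled alignment in either supported dialect.

    ``stockholm_markup``: Stockholm with ``#=GC RF`` and ``#=GR .. PPI``.
    ``annotated_fasta``: FASTA with a ``__RF__`` record and a
    ``<seqid> __PPI__`` label record after each sequence.
    """
    path = Path(path)
    if dialect == "stockholm_markup":
        return _read_stockholm(path)
    if dialect == "annotated_fasta":
        return _read_annotated_fasta(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_stockholm(path: Path) -> LabeledAlignment:
    family_id = path.stem
    domain_role = "A"
    rows: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    labels: dict[str, str] = {}
    rf_parts: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# STOCKHOLM"):
            raise FormatError(f"{path}: missing '# STOCKHOLM' header")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line == "//":
                continue
            if line.startswith("#=GF ID"):
                family_id = line.split(None, 2)[2]
            elif line.startswith("#=GF CC"):
                comment = line.split(None, 2)[2]
                if comment.startswith("domain_role:"):
                    domain_role = comment.split(":", 1)[1].strip()
            elif line.startswith("#=GR"):
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError(f"{path}: malformed #=GR line: {line!r}")
                _, seq_id, tag, text = parts
                if tag == "PPI":
                    labels[seq_id] = labels.get(seq_id, "") + text
            elif line.startswith("#=GC"):
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"{path}: malformed #=GC line: {line!r}")
                if parts[1] == "RF":
                    rf_parts.append(parts[2])
            elif line.startswith("#"):
                continue
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"{path}: malformed sequence line: {line!r}")
                seq_id, chunk = parts
                if seq_id in seen:
                    idx = seen[seq_id]
                    rows[idx] = (seq_id, rows[idx][1] + chunk)
                else:
                    seen[seq_id] = len(rows)
                    rows.append((seq_id, chunk))
    if not rf_parts:
        raise FormatError(f"{path}: missing '#=GC RF' reference line")
    return _assemble_alignment(family_id, domain_role, rows, "".join(rf_parts),
                               labels, str(path))


def _read_annotated_fasta(path: Path) -> LabeledAlignment:
    family_id = path.stem
    domain_role = "A"
    rows: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    rf: str | None = None
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            fields = title.split()
            name = fields[0]
            if name == "__RF__":
                rf = seq
                for kv in fields[1:]:
                    if "=" in kv:
                        key, val = kv.split("=", 1)
                        if key == "family_id":
                            family_id = val
                        elif key == "domain_role":
                            domain_role = val
            elif len(fields) > 1 and fields[1] == "__PPI__":
                labels[name] = seq
            else:
                rows.append((name, seq))
    if rf is None:
        raise FormatError(f"{path}: missing '__RF__' reference record")
    return _assemble_alignment(family_id, domain_role, rows, rf, labels,
                               str(path))


def write_labeled_alignment(aln: LabeledAlignment, path: str | Path,
                            dialect: str = "stockholm_markup") -> None:
    path = Path(path)
    rf = "".join("x" if i in set(aln.match_columns) else "."
                 for i in range(aln.width))
    label_strings = {}
    for seq_id, _ in aln.rows:
        labels = {c: aln.site_labels[(seq_id, c)] for c in aln.match_columns}
        label_strings[seq_id] = _labels_to_string(
            aln.width, aln.match_columns, aln.aligned(seq_id), labels)
    if dialect == "stockholm_markup":
        name_w = max(len("#=GC RF"),
                     *(len(f"#=GR {sid} PPI") for sid in aln.seq_ids))
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            fh.write(f"#=GF ID {aln.family_id}\n")
            fh.write(f"#=GF CC domain_role: {aln.domain_role}\n")
            for seq_id, seq in aln.rows:
                fh.write(f"{seq_id:<{name_w}} {seq}\n")
                fh.write(f"{f'#=GR {seq_id} PPI':<{name_w}} "
                         f"{label_strings[seq_id]}\n")
            fh.write(f"{'#=GC RF':<{name_w}} {rf}\n")
            fh.write("//\n")
    elif dialect == "annotated_fasta":
        with open(path, "w") as fh:
            fh.write(f">__RF__ family_id={aln.family_id} "
                     f"domain_role={aln.domain_role}\n{rf}\n")
            for seq_id, seq in aln.rows:
                fh.write(f">{seq_id}\n{seq}\n")
                fh.write(f">{seq_id} __PPI__\n{label_strings[seq_id]}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# AAindex property tables
# ---------------------------------------------------------------------------

@dataclass
class AAIndexTable:
    """Ordered set of amino-acid property scales.

    ``properties`` maps each accession to a 20-value dict keyed by
    residue letter; the order of ``properties`` fixes the feature order
    of every downstream window vector.
    """

    properties: list[tuple[str, dict[str, float]]]

    def __post_init__(self) -> None:
        for acc, values in self.properties:
            if set(values) != set(AMINO_ACIDS):
                raise ValidationError(
                    f"property {acc} must define all 20 residues")
            if not all(np.isfinite(v) for v in values.values()):
                raise ValidationError(f"property {acc} has non-finite values")

    @property
    def accessions(self) -> list[str]:
        return [acc for acc, _ in self.properties]

    def __len__(self) -> int:
        return len(self.properties)

    def matrix(self) -> np.ndarray:
        """(n_properties, 20) array in canonical residue order."""
        return np.array([[values[aa] for aa in AMINO_ACIDS]
                         for _, values in self.properties])


def read_aaindex(path: str | Path,
                 accessions: Sequence[str] | None = None) -> AAIndexTable:
    """Parse an AAindex1 flat file and return the requested accessions.

    ``accessions`` defaults to the package's 17 physicochemical scales;
    the returned table follows the requested order exactly.
    """
    if accessions is None:
        accessions = DEFAULT_AAINDEX_ACCESSIONS
    records: dict[str, dict[str, float]] = {}
    current: str | None = None
    value_rows: list[str] = []
    in_values = False

    def _finish() -> None:
        nonlocal current, value_rows, in_values
        if current is not None and value_rows:
            tokens = " ".join(value_rows).split()
            if len(tokens) != 20:
                raise FormatError(
                    f"{path}: record {current} has {len(tokens)} values, "
                    "expected 20")
            values: dict[str, float] = {}
            for aa, tok in zip(AAINDEX_ROW1 + AAINDEX_ROW2, tokens):
                if tok.upper() == "NA":
                    raise FormatError(
                        f"{path}: record {current} has 'NA' for residue {aa}")
                try:
                    values[aa] = float(tok)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: record {current}: malformed value "
                        f"{tok!r}") from exc
            records[current] = values
        current, value_rows, in_values = None, [], False

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("//"):
                _finish()
            elif line.startswith("H "):
                current = line[2:].strip()
            elif line.startswith("I "):
                in_values = True
            elif in_values and line.startswith(" "):
                value_rows.append(line)
            elif line[:1].isalpha():
                in_values = False
    _finish()

    missing = [acc for acc in accessions if acc not in records]
    if missing:
        raise ValidationError(
            f"{path}: accessions not found: {', '.join(missing)}")
    return AAIndexTable([(acc, records[acc]) for acc in accessions])


def default_aaindex_table() -> AAIndexTable:
    """The packaged 17-property table (synthetic stand-in values)."""
    from importlib.resources import files
    path = files("cmiphmm.data") / "aaindex17_synthetic.txt"
    return read_aaindex(str(path))


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

CONTACT_KINDS = ("ground_truth", "predicted_binary", "predicted_score")


@dataclass
class ContactMatrix:
    """Residue-residue contact matrix in match-state coordinates.

    Rows index match states of domain A, columns match states of
    domain B, so the matrix shape is constant across family members.
    ``kind`` distinguishes the binary ground truth, the binarized
    prediction and the raw classifier scores.
    """

    family_id: str
    pair_id: str
    cells: np.ndarray
    kind: str
    length_bound: int = DEFAULT_LENGTH_BOUND

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.kind not in CONTACT_KINDS:
            raise ValidationError(f"unknown contact-matrix kind {self.kind!r}")
        if self.cells.ndim != 2 or min(self.cells.shape) < 1:
            raise ValidationError("contact matrix must be 2-D and non-empty")
        n, m = self.cells.shape
        if n + m > self.length_bound:
            raise ValidationError(
                f"summed domain lengths {n}+{m} exceed the bound "
                f"{self.length_bound}")
        if not np.all(np.isfinite(self.cells)):
            raise ValidationError("contact matrix has non-finite cells")
        if self.kind in ("ground_truth", "predicted_binary"):
            if not np.isin(self.cells, (0.0, 1.0)).all():
                bad = self.cells[~np.isin(self.cells, (0.0, 1.0))][0]
                raise FormatError(
                    f"non-binary cell value {bad} under kind={self.kind}")

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]


def read_contact_matrix(path: str | Path) -> ContactMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#kind="):
        raise FormatError(f"{path}: missing '#kind=' header line")
    meta = dict(kv.split("=", 1) for kv in header[1:].split())
    kind = meta.get("kind", "")
    df = pd.read_csv(path, sep="\t", skiprows=1, index_col=0)
    try:
        cells = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    return ContactMatrix(family_id=meta.get("family_id", path.stem),
                         pair_id=meta.get("pair_id", path.stem),
                         cells=cells, kind=kind)


def write_contact_matrix(cm: ContactMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        cm.cells,
        index=np.arange(1, cm.n_rows + 1),
        columns=np.arange(1, cm.n_cols + 1),
    )
    if cm.kind in ("ground_truth", "predicted_binary"):
        df = df.astype(int)
    with open(path, "w") as fh:
        fh.write(f"#kind={cm.kind} family_id={cm.family_id} "
                 f"pair_id={cm.pair_id}\n")
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Prediction reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["family_id", "pair_id", "domain_role", "seq_id",
                  "match_index", "label_true", "label_pred", "score"]


def write_predictions_report(records: Iterable[dict] | pd.DataFrame,
                             path: str | Path,
                             header_comment: str | None = None) -> None:
    """Write per-residue predictions as TSV (1-based match indices)."""
    df = pd.DataFrame(records)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"report missing columns: {missing}")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df[REPORT_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_predictions_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
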