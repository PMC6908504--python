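"""Reading, writing and assembling labeled protein corpora.

The on-disk formats are deliberately plain: FASTA for sequences, PSI-BLAST
``-out_ascii_pssm`` files for evolutionary profiles (one file per protein,
named ``<id>.pssm``), a three-column long-format TSV for annotation keyword
sets, and a two-column TSV for binary labels (1 = acetylated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Recognized annotation vocabularies: Gene Ontology, five protein family /
#: domain databases, PRINTS motif fingerprints, and subcellular localization.
SOURCES: tuple[str, ...] = (
    "GO", "Pfam", "Smart", "PROSITE", "SUPFAM", "InterPro", "PRINTS", "SL",
)
_SOURCE_BY_LOWER = {s.lower(): s for s in SOURCES}
#: Aliases accepted on input.
_SOURCE_BY_LOWER["subcellular localization"] = "SL"
_SOURCE_BY_LOWER["smart"] = "Smart"

#: Canonical residue alphabet (alphabetical single-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: PSI-BLAST prints PSSM columns in this residue order.
PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Deterministic replacements for ambiguity codes; '*' and gap characters
#: are dropped outright.
SANITIZE_MAP = {"B": "N", "Z": "Q", "U": "C", "O": "K", "X": "A"}
_DROP_CHARS = set("*-. ")


class CorpusError(ValueError):
    """Raised for malformed input files or inconsistent corpora."""


@dataclass
class ProteinRecord:
    """One protein: sequence, optional label, annotation sets, optional PSSM.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header up to the first whitespace).
    sequence : str
        Canonical 20-letter amino-acid string.
    label : int or None
        1 = acetylated, 0 = non-acetylated, None = unknown.
    annotations : mapping of source -> frozenset of keyword strings
        Sources absent from the mapping are treated as empty sets.
    pssm : ndarray or None
        L x 20 log-odds matrix, columns in :data:`PSSM_AA_ORDER`.
    """

    id: str
    sequence: str
    label: Optional[int] = None
    annotations: Mapping[str, frozenset] = field(default_factory=dict)
    pssm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise CorpusError(
                f"record {self.id!r}: non-canonical residues {sorted(bad)}; "
                "run sanitize_sequence first"
            )
        if self.pssm is not None:
            self.pssm = np.asarray(self.pssm)
            if self.pssm.shape != (len(self.sequence), 20):
                raise CorpusError(
                    f"record {self.id!r}: PSSM shape {self.pssm.shape} does not "
                    f"match sequence length {len(self.sequence)}"
                )

    def annotation_set(self, source: str) -> frozenset:
        return frozenset(self.annotations.get(source, frozenset()))


@dataclass
class Corpus:
    """An ordered collection of :class:`ProteinRecord` with unique ids.

    ``partition`` optionally maps each record id to one of
    ``{"posi", "neg1", "neg2", "neg3"}`` — the balanced-dataset layout in
    which the negative pool is split into three disjoint subsets, each the
    size of the positive set.
    """

    records: list
    partition: Optional[dict] = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusError(f"duplicate record ids: {dupes[:5]}")
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> ProteinRecord:
        return self._by_id[rec_id]

    @property
    def ids(self) -> list:
        return [r.id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def positives(self) -> list:
        return [r for r in self.records if r.label == 1]

    def negatives(self) -> list:
        return [r for r in self.records if r.label == 0]

    def subset(self, rec_ids: Sequence[str]) -> "Corpus":
        return Corpus(records=[self._by_id[i] for i in rec_ids])


def sanitize_sequence(raw: str) -> str:
    """Uppercase and map ambiguity codes to canonical residues.

    B->N, Z->Q, U->C, O->K, X->A; ``*``, gaps and whitespace are dropped.
    Any other unknown character raises :class:`CorpusError`.
    """
    out = []
    for ch in raw.upper():
        if ch in _DROP_CHARS:
            continue
        ch = SANITIZE_MAP.get(ch, ch)
        if ch not in AMINO_ACIDS:
            raise CorpusError(f"unmappable residue character {ch!r}")
        out.append(ch)
    return "".join(out)


def read_fasta(path) -> list:
    """Read a FASTA file into ``[(id, sanitized_sequence), ...]`` in file order.

    Ids are the header up to the first whitespace; sequences are uppercased
    and sanitized. A file whose first non-blank line is not a header is a
    parse error naming that line; an empty file yields ``[]`` with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise CorpusError(
                f"{path}: line {lineno}: sequence data before any FASTA header"
            )
        break
    else:
        logger.warning("%s: empty FASTA file", path)
        return []
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, sanitize_sequence(str(rec.seq))))
    return out


def write_fasta(records, path, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs (or ProteinRecords) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if isinstance(rec, ProteinRecord) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pssm(path) -> np.ndarray:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into an L x 20 log-odds matrix.

    Only the first 20 (log-odds) columns are kept. Columns are returned
    reordered into :data:`PSSM_AA_ORDER` regardless of the header order the
    file declares. Rows follow sequence position order; non-contiguous
    position indices or short rows are parse errors naming the line.
    """
    path = Path(path)
    header_order = None
    rows = []
    expected_pos = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                if rows:
                    break  # footer separator after the matrix block
                continue
            if header_order is None:
                if len(tokens) >= 40 and all(t in PSSM_AA_ORDER for t in tokens[:40]):
                    header_order = tokens[:20]
                continue
            if not tokens[0].isdigit():
                break  # reached Lambda/K footer lines
            if len(tokens) < 22:
                raise CorpusError(
                    f"{path}: line {lineno}: expected >=22 tokens, got {len(tokens)}"
                )
            pos = int(tokens[0])
            if pos != expected_pos:
                raise CorpusError(
                    f"{path}: line {lineno}: position index {pos} not contiguous "
                    f"(expected {expected_pos})"
                )
            expected_pos += 1
            try:
                rows.append([float(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise CorpusError(f"{path}: line {lineno}: {exc}") from exc
    if header_order is None or not rows:
        raise CorpusError(f"{path}: no PSSM matrix block found")
    mat = np.array(rows)
    order = [header_order.index(aa) for aa in PSSM_AA_ORDER]
    return mat[:, order]


def write_pssm(sequence: str, matrix: np.ndarray, path) -> None:
    """Write an L x 20 matrix (columns in :data:`PSSM_AA_ORDER`) in the
    PSI-BLAST ASCII dialect that :func:`read_pssm` consumes.

    The weighted-percentage block and the two trailing per-row reals are
    filled with zeros; only the log-odds block is meaningful.
    """
    matrix = np.asarray(matrix)
    if matrix.shape != (len(sequence), 20):
        raise CorpusError(
            f"matrix shape {matrix.shape} does not match sequence length {len(sequence)}"
        )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        aa_cols = "  ".join(PSSM_AA_ORDER)
        fh.write(f"            {aa_cols}   {aa_cols}\n")
        for i, (res, row) in enumerate(zip(sequence, matrix), 1):
            scores = " ".join(f"{int(round(v)):3d}" for v in row)
            pcts = " ".join("  0" for _ in range(20))
            fh.write(f"{i:5d} {res}  {scores}  {pcts}  0.00 0.00\n")
        fh.write("\n")


def read_annotations(path) -> dict:
    """Read a 3-column TSV (protein_id, source, keyword) into nested sets.

    Source names are matched case-insensitively against :data:`SOURCES`;
    unknown sources and rows with the wrong column count are errors naming
    the line. Duplicate rows collapse under set semantics. A header row
    starting with ``protein_id`` is skipped.
    """
    path = Path(path)
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise CorpusError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            rid, source, keyword = (f.strip() for f in fields)
            if lineno == 1 and rid.lower() in {"protein_id", "id"}:
                continue
            canonical = _SOURCE_BY_LOWER.get(source.lower())
            if canonical is None:
                raise CorpusError(
                    f"{path}: line {lineno}: unknown source {source!r}; "
                    f"accepted: {', '.join(SOURCES)}"
                )
            out.setdefault(rid, {}).setdefault(canonical, set()).add(keyword)
    return {
        rid: {src: frozenset(kws) for src, kws in per.items()}
        for rid, per in out.items()
    }


def write_annotations(corpus: Corpus, path) -> None:
    """Write a corpus's annotation sets as the 3-column TSV, sorted for
    byte-stable output."""
    with open(path, "w") as fh:
        fh.write("protein_id\tsource\tkeyword\n")
        for rec in corpus:
            for source in SOURCES:
                for kw in sorted(rec.annotation_set(source)):
                    fh.write(f"{rec.id}\t{source}\t{kw}\n")


def read_labels(path) -> dict:
    """Read a 2-column TSV of (protein_id, {0,1}) into a dict."""
    path = Path(path)
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise CorpusError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            rid, lab = fields[0].strip(), fields[1].strip()
            if lineno == 1 and rid.lower() in {"protein_id", "id"}:
                continue
            if lab not in {"0", "1"}:
                raise CorpusError(f"{path}: line {lineno}: label must be 0 or 1")
            out[rid] = int(lab)
    return out


def write_labels(corpus: Corpus, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tlabel\n")
        for rec in corpus:
            fh.write(f"{rec.id}\t{rec.label}\n")


def load_corpus(
    fasta_path,
    annotations_path=None,
    labels_path=None,
    pssm_dir=None,
    missing_pssm: str = "error",
    min_length: int = 30,
) -> Corpus:
    """Assemble a :class:`Corpus` from on-disk files.

    ``missing_pssm`` controls proteins without a ``<id>.pssm`` file when
    ``pssm_dir`` is given: ``"error"`` raises, ``"zero"`` records an all-zero
    L x 20 profile, ``"drop"`` silently excludes the protein. Sequences
    shorter than ``min_length`` (training filter: 30) are dropped with a
    warning.
    """
    if missing_pssm not in {"error", "zero", "drop"}:
        raise ValueError("missing_pssm must be 'error', 'zero' or 'drop'")
    annotations = read_annotations(annotations_path) if annotations_path else {}
    labels = read_labels(labels_path) if labels_path else {}
    records = []
    for rid, seq in read_fasta(fasta_path):
        if len(seq) < min_length:
            logger.warning("dropping %s: length %d < %d", rid, len(seq), min_length)
            continue
        pssm = None
        if pssm_dir is not None:
            pssm_file = Path(pssm_dir) / f"{rid}.pssm"
            if pssm_file.exists():
                pssm = read_pssm(pssm_file)
            elif missing_pssm == "zero":
                pssm = np.zeros((len(seq), 20))
            elif missing_pssm == "drop":
                logger.warning("dropping %s: no PSSM file", rid)
                continue
            else:
                raise CorpusError(f"no PSSM file for {rid} in {pssm_dir}")
        records.append(
            ProteinRecord(
                id=rid,
                sequence=seq,
                label=labels.get(rid),
                annotations=annotations.get(rid, {}),
                pssm=pssm,
            )
        )
    return Corpus(records=records)


def partition_negatives(corpus: Corpus, seed: int) -> Corpus:
    """Split the negatives into three disjoint subsets of near-equal size.

    The negative pool is shuffled with ``seed`` and dealt into three subsets
    whose sizes differ by at most one (e.g. 2175 -> 725/725/725); positives
    are untouched. Returns a new Corpus with the partition recorded.
    """
    negatives = corpus.negatives()
    if len(negatives) < 3:
        raise CorpusError(
            f"need at least 3 negatives to partition, got {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(negatives))
    shuffled = [negatives[i] for i in order]
    n = len(shuffled)
    base, extra = divmod(n, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    partition = {r.id: "posi" for r in corpus.positives()}
    start = 0
    for i, size in enumerate(sizes, 1):
        for rec in shuffled[start : start + size]:
            partition[rec.id] = f"neg{i}"
        start += size
    return Corpus(records=list(corpus.records), partition=partition)


def balanced_datasets(corpus: Corpus) -> list:
    """Return the three balanced corpora ``S_posi ∪ S_i^-`` implied by the
    recorded partition (corpus order preserved)."""
    if corpus.partition is None:
        raise CorpusError("corpus has no partition; call partition_negatives first")
    out = []
    for i in (1, 2, 3):
        keep = {"posi", f"neg{i}"}
        recs = [r for r in corpus.records if corpus.partition.get(r.id) in keep]
        out.append(Corpus(records=recs))
    return out
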