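"""AIRR rearrangement I/O and native V/D/J assignment.

Reads and writes AIRR rearrangement TSV tables and provides a native
segment assigner: V and J segments are scored against protocol-windowed
references with a local prefix/suffix alignment (ties preserved as
multi-calls), the D segment by the longest exact germline substring match
inside the junction, and productivity from junction frame and stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trbkit.reference import (
    AllelePatternGroup,
    GermlineSet,
    ProtocolSpec,
    collapse_patterns,
    merge_indistinguishable,
    window,
    window_offset,
)

#: columns always written, in AIRR order
AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_length",
    "cdr3_length",
    "productive",
    "v_mismatches",
    "v_snps",
    "v_alignment_length",
    "d_matched_length",
    "sample_id",
]

MANDATORY_COLUMNS = ["sequence_id", "sequence"]

_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class Rearrangement:
    """One assigned V(D)J read."""

    sequence_id: str
    sequence: str
    v_call: list[str] = field(default_factory=list)
    d_call: list[str] = field(default_factory=list)
    j_call: list[str] = field(default_factory=list)
    v_mismatches: int = 0
    v_snps: list[str] = field(default_factory=list)
    v_alignment_length: int = 0
    d_matched_length: int = 0
    junction: str = ""
    junction_length: int = 0
    cdr3_length: int = 0
    productive: bool | None = None
    sample_id: str = ""


class Repertoire:
    """One sample's rearrangement table plus its protocol.

    Counts throughout the package are over unique sequences; the table is
    deduplicated on the nucleotide sequence at construction.
    """

    def __init__(self, df: pd.DataFrame, sample_id: str = "", protocol=None,
                 dedup: bool = True):
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing mandatory AIRR column {col!r}")
        dup = df["sequence_id"][df["sequence_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicated sequence_id: {dup.iloc[0]!r}")
        if dedup and len(df):
            df = df.drop_duplicates(subset="sequence").reset_index(drop=True)
        self.df = df.reset_index(drop=True)
        self.sample_id = sample_id or (
            str(df["sample_id"].iloc[0]) if "sample_id" in df and len(df) else ""
        )
        self.protocol = protocol

    def __len__(self):
        return len(self.df)

    def records(self):
        for row in self.df.itertuples(index=False):
            yield Rearrangement(
                sequence_id=row.sequence_id,
                sequence=row.sequence,
                v_call=_split(getattr(row, "v_call", "")),
                d_call=_split(getattr(row, "d_call", "")),
                j_call=_split(getattr(row, "j_call", "")),
                v_mismatches=int(getattr(row, "v_mismatches", 0) or 0),
                v_snps=_split(getattr(row, "v_snps", ""), sep=";"),
                v_alignment_length=int(getattr(row, "v_alignment_length", 0) or 0),
                d_matched_length=int(getattr(row, "d_matched_length", 0) or 0),
                junction=str(getattr(row, "junction", "") or ""),
                junction_length=int(getattr(row, "junction_length", 0) or 0),
                cdr3_length=int(getattr(row, "cdr3_length", 0) or 0),
                productive=_parse_bool(getattr(row, "productive", "")),
                sample_id=str(getattr(row, "sample_id", "") or ""),
            )


def _split(value, sep=",") -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    s = str(value)
    return [t for t in s.split(sep) if t] if s else []


def split_call(call: str) -> tuple[str, str]:
    """Split a call into (gene label, allele label).

    Handles plain calls (``TRBV7-2*02``), partial-pattern calls on merged
    genes (``TRBV6-2/TRBV6-3*bp01``) and full-protocol merged-allele labels
    (``TRBV6-2*01/TRBV6-3*01`` -> gene ``TRBV6-2/TRBV6-3``, allele ``01``).
    """
    if call.count("*") <= 1:
        gene, _, allele = call.partition("*")
        return gene, allele or "01"
    parts = call.split("/")
    genes = [p.split("*")[0] for p in parts]
    alleles = sorted({p.split("*")[1] for p in parts if "*" in p})
    return "/".join(genes), "/".join(alleles)


def _parse_bool(value):
    s = str(value)
    if s in ("T", "True", "true"):
        return True
    if s in ("F", "False", "false"):
        return False
    return None


def read_airr(tsv_source, protocol=None) -> Repertoire:
    """Read an AIRR rearrangement TSV into a :class:`Repertoire`.

    Unknown columns are preserved; a missing mandatory column is a hard
    error.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory AIRR column {col!r}")
    for col in ("v_mismatches", "v_alignment_length", "d_matched_length",
                "junction_length", "cdr3_length"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    return Repertoire(df, protocol=protocol, dedup=False)


def write_airr(repertoire: Repertoire, tsv_target) -> None:
    """Write a repertoire back to AIRR TSV, known columns first."""
    df = repertoire.df.copy()
    cols = [c for c in AIRR_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(tsv_target, sep="\t", index=False)


# ---------------------------------------------------------------------------
# assignment


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _find_cys(seq: str) -> int | None:
    """Rightmost codon-aligned TGT/TGC — the conserved second Cys of FR3."""
    for i in range(3 * ((len(seq) - 3) // 3), -1, -3):
        if seq[i : i + 3] in ("TGT", "TGC"):
            return i
    return None


def _find_phe(seq: str) -> int | None:
    """Start of the J-gene F/W-G-x-G motif (TTTGG/TTCGG/TGGGG)."""
    for motif in ("TTTGG", "TTCGG", "TGGGG"):
        i = seq.find(motif)
        if i >= 0:
            return i
    return None


@dataclass
class _RefBank:
    """Padded uint8 matrix over reference sequences for vectorised scoring."""

    names: list[str]
    seqs: list[str]
    matrix: np.ndarray  # (n_refs, max_len)
    lengths: np.ndarray
    imgt: list[np.ndarray]  # per ref, IMGT position of each index
    anchor: list[int | None]  # Cys index (V) or Phe motif index (J)

    @classmethod
    def build(cls, entries, reverse=False):
        names, seqs, imgt, anchor = [], [], [], []
        for name, seq, positions, anc in entries:
            names.append(name)
            seqs.append(seq)
            imgt.append(np.asarray(positions, dtype=np.int64))
            anchor.append(anc)
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        maxlen = int(lengths.max())
        matrix = np.zeros((len(seqs), maxlen), dtype=np.uint8)
        for i, s in enumerate(seqs):
            v = _encode(s[::-1] if reverse else s)
            matrix[i, : len(v)] = v
        return cls(names, seqs, matrix, lengths, imgt, anchor)


MISMATCH_PENALTY = 4  # score = matches - 3*mismatches over the aligned prefix


def _score_bank(bank: _RefBank, read: np.ndarray):
    """Best local prefix score of each reference against ``read``.

    Returns (scores, best_lengths, cummismatch matrix): the score of ref r
    at aligned length L is ``L - 4*mismatches(L)``; the best L (longest on
    ties) is reported per reference.
    """
    lc = min(bank.matrix.shape[1], len(read))
    cmp = bank.matrix[:, :lc] != read[None, :lc]
    cum = np.cumsum(cmp, axis=1)
    ls = np.arange(1, lc + 1, dtype=np.int64)
    scores = ls[None, :] - MISMATCH_PENALTY * cum
    # lengths beyond each reference are invalid
    invalid = ls[None, :] > bank.lengths[:, None]
    scores = np.where(invalid, np.iinfo(np.int64).min, scores)
    # longest L on score ties: scan from the right
    best_len = lc - np.argmax(scores[:, ::-1], axis=1)
    best = scores[np.arange(len(bank.names)), best_len - 1]
    return best, best_len, cum


def _longest_common_substring(a: str, b: str) -> tuple[int, int]:
    """Length and start-in-``b`` of the longest common substring."""
    best, best_jb = 0, 0
    la, lb = len(a), len(b)
    for shift in range(-(lb - 1), la):
        run = 0
        for j in range(lb):
            i = j + shift
            if 0 <= i < la and a[i] == b[j]:
                run += 1
                if run > best:
                    best, best_jb = run, j - run + 1
            else:
                run = 0
    return best, best_jb


class Assigner:
    """V/D/J segment assigner over protocol-collapsed pattern references.

    Ties in V and J are kept as multi-calls (the downstream genotyping
    filter needs the "only one best match" signal); D assignment is the
    longest exact substring match of a D allele inside the junction region,
    with no mismatches allowed.
    """

    def __init__(
        self,
        v_set: GermlineSet,
        d_set: GermlineSet,
        j_set: GermlineSet,
        protocol: ProtocolSpec | None = None,
        min_d_match: int = 5,
        min_v_score: int = 12,
        boundary_end: int = 316,
        boundary_margin: int = 5,
    ):
        self.protocol = protocol or ProtocolSpec("full")
        self.min_d_match = min_d_match
        self.min_v_score = min_v_score
        self.boundary_end = boundary_end
        self.boundary_margin = boundary_margin

        merged = merge_indistinguishable(v_set, self.protocol)
        self.v_patterns: list[AllelePatternGroup] = collapse_patterns(
            merged, self.protocol
        )
        v_entries = []
        for p in self.v_patterns:
            members = [
                a
                for gene, al in p.members
                for a in merged.alleles(gene)
                if a.allele == al
            ]
            longest = max(members, key=lambda a: len(a.sequence))
            off = window_offset(longest, self.protocol)
            positions = longest.gapped_map[off:]
            v_entries.append(
                (p.pattern_name, p.representative, positions,
                 _find_cys(p.representative))
            )
        self.v_bank = _RefBank.build(v_entries)

        j_entries = [
            (a.name, a.sequence, a.gapped_map, _find_phe(a.sequence))
            for a in j_set
        ]
        self.j_bank = _RefBank.build(j_entries, reverse=True)
        self.d_alleles = [(a.name, a.sequence) for a in d_set]

    # -- per-read -----------------------------------------------------------

    def assign(self, sequence: str, sequence_id: str = "", sample_id: str = "") -> Rearrangement:
        """Assign one read; unusable reads keep empty calls."""
        rec = Rearrangement(sequence_id=sequence_id, sequence=sequence,
                            sample_id=sample_id)
        read = _encode(sequence)
        if len(read) < 10:
            return rec

        # V: prefix-anchored local score
        v_scores, v_lens, v_cum = _score_bank(self.v_bank, read)
        v_best = int(v_scores.max())
        if v_best < self.min_v_score:
            return rec
        v_idx = np.flatnonzero(v_scores == v_best)
        # deterministic call order
        rec.v_call = sorted(self.v_bank.names[i] for i in v_idx)
        i0 = int(v_idx[0])
        v_len = int(v_lens[i0])
        rec.v_alignment_length = v_len

        # mismatch tokens within the boundary window, on the first best ref
        ref = self.v_bank.seqs[i0]
        imgt = self.v_bank.imgt[i0]
        b_start = int(imgt[0]) + self.boundary_margin
        snps = []
        n_window = 0
        mism = np.flatnonzero(
            self.v_bank.matrix[i0, :v_len] != read[:v_len]
        )
        for i in mism:
            pos = int(imgt[i])
            if b_start <= pos <= self.boundary_end:
                n_window += 1
                snps.append(f"{ref[i]}{pos}{chr(read[i])}")
        rec.v_mismatches = n_window
        rec.v_snps = snps

        # J: suffix-anchored local score on reversed read
        j_scores, j_lens, _ = _score_bank(self.j_bank, read[::-1])
        j_best = int(j_scores.max())
        if j_best < 6:
            return rec
        j_idx = np.flatnonzero(j_scores == j_best)
        rec.j_call = sorted(self.j_bank.names[i] for i in j_idx)
        j0 = int(j_idx[0])
        j_overlap = int(j_lens[j0])
        j_start = len(sequence) - j_overlap  # read index where J begins
        j_ref_off = int(self.j_bank.lengths[j0]) - j_overlap

        # D: longest exact substring in the junction region
        region = sequence[v_len:j_start]
        if region:
            best_len = 0
            calls = []
            for name, dseq in self.d_alleles:
                ln, _ = _longest_common_substring(dseq, region)
                if ln > best_len:
                    best_len, calls = ln, [name]
                elif ln == best_len and ln > 0:
                    calls.append(name)
            if best_len >= self.min_d_match:
                rec.d_call = sorted(calls)
                rec.d_matched_length = best_len

        # junction: conserved V Cys codon through J Phe motif + 3
        cys = self.v_bank.anchor[i0]
        phe = self.j_bank.anchor[j0]
        if cys is not None and phe is not None and cys < v_len:
            j_end = j_start + (phe - j_ref_off) + 3
            if j_start - j_ref_off >= 0 and cys < j_end <= len(sequence):
                rec.junction = sequence[cys:j_end]
                rec.junction_length = len(rec.junction)
                rec.cdr3_length = max(rec.junction_length - 6, 0)
                rec.productive = classify_functionality(rec.junction)
        return rec

    def assign_repertoire(self, sequences, sample_id: str = "",
                          ids=None) -> Repertoire:
        """Assign a list of raw reads and return an AIRR repertoire."""
        rows = []
        for k, seq in enumerate(sequences):
            sid = ids[k] if ids is not None else f"{sample_id}_{k}"
            rec = self.assign(seq, sequence_id=sid, sample_id=sample_id)
            rows.append(
                {
                    "sequence_id": rec.sequence_id,
                    "sequence": rec.sequence,
                    "v_call": ",".join(rec.v_call),
                    "d_call": ",".join(rec.d_call),
                    "j_call": ",".join(rec.j_call),
                    "junction": rec.junction,
                    "junction_length": rec.junction_length,
                    "cdr3_length": rec.cdr3_length,
                    "productive": {True: "T", False: "F", None: ""}[rec.productive],
                    "v_mismatches": rec.v_mismatches,
                    "v_snps": ";".join(rec.v_snps),
                    "v_alignment_length": rec.v_alignment_length,
                    "d_matched_length": rec.d_matched_length,
                    "sample_id": sample_id,
                }
            )
        df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
        return Repertoire(df, sample_id=sample_id, protocol=self.protocol)


def classify_functionality(junction: str) -> bool | None:
    """Productive iff the junction is in frame and stop-free.

    The junction starts at the conserved V Cys codon (a codon boundary), so
    a length not divisible by 3 means a V-to-J frame shift; any stop codon
    read in that frame is also non-functional.  An empty junction is
    unknown.
    """
    if not junction:
        return None
    if len(junction) % 3 != 0:
        return False
    for i in range(0, len(junction) - 2, 3):
        if junction[i : i + 3] in _STOP_CODONS:
            return False
    return True
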