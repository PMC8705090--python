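"""miR reference database: precursor hairpins plus located mature arms.

A reference is a set of precursor (hairpin) sequences, each carrying up to
two mature arms (5p and 3p) located by 0-based half-open coordinates inside
the precursor.  Arms are the units that reads are classified against; the
precursor context around an arm decides whether a 3' extension of a read is
templated (encoded in the hairpin) or a non-templated addition.

Sequences are stored as RNA (``ACGU``); DNA input is converted on load.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

COORDS_COLUMNS = ["precursor_id", "mature_name", "start", "end", "arm"]


class ReferenceLoadError(ValueError):
    """Raised when a hairpin FASTA + coordinates table pair is inconsistent."""


def normalize_rna(sequence: str, *, where: str = "sequence") -> str:
    """Uppercase and convert T to U; reject anything outside {A,C,G,U}."""
    seq = sequence.strip().upper().replace("T", "U")
    if not seq:
        raise ReferenceLoadError(f"{where}: empty sequence")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ReferenceLoadError(
            f"{where}: invalid characters {sorted(bad)!r}; expected RNA/DNA letters"
        )
    return seq


@dataclass(frozen=True)
class ReferenceMiR:
    """A mature arm located at [start, end) within its precursor."""

    name: str
    precursor_id: str
    start: int
    end: int
    arm: str  # "5p" or "3p"
    sequence: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ReferenceLoadError(
                f"arm {self.name!r}: arm must be '5p' or '3p', got {self.arm!r}"
            )
        if not (0 <= self.start < self.end):
            raise ReferenceLoadError(
                f"arm {self.name!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Precursor:
    """A hairpin sequence with its located mature arms."""

    id: str
    sequence: str
    arms: list[ReferenceMiR] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence, where=f"precursor {self.id!r}")


@dataclass
class ReferenceSet:
    """All precursors plus a flat name -> arm index."""

    precursors: dict[str, Precursor]
    arms_by_name: dict[str, ReferenceMiR]

    def arm(self, name: str) -> ReferenceMiR:
        return self.arms_by_name[name]

    def precursor_of(self, arm: ReferenceMiR | str) -> Precursor:
        if isinstance(arm, str):
            arm = self.arms_by_name[arm]
        return self.precursors[arm.precursor_id]

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for pre in self.precursors.values():
            if len(pre.arms) > 2:
                raise ReferenceLoadError(
                    f"precursor {pre.id!r}: more than two arms"
                )
            ordered = sorted(pre.arms, key=lambda a: a.start)
            for a, b in zip(ordered, ordered[1:]):
                if a.end > b.start:
                    raise ReferenceLoadError(
                        f"precursor {pre.id!r}: arms {a.name!r} and {b.name!r} overlap"
                    )
            for arm in pre.arms:
                if arm.precursor_id != pre.id:
                    raise ReferenceLoadError(
                        f"arm {arm.name!r}: precursor_id {arm.precursor_id!r} != {pre.id!r}"
                    )
                if arm.end > len(pre.sequence):
                    raise ReferenceLoadError(
                        f"arm {arm.name!r}: coordinates out of bounds "
                        f"[{arm.start}, {arm.end}) on {len(pre.sequence)}-nt precursor {pre.id!r}"
                    )
                if arm.sequence != pre.sequence[arm.start:arm.end]:
                    raise ReferenceLoadError(
                        f"arm {arm.name!r}: stored sequence does not match "
                        f"precursor {pre.id!r}[{arm.start}:{arm.end}]"
                    )
                if arm.name in seen:
                    raise ReferenceLoadError(
                        f"duplicate mature name {arm.name!r} on precursors "
                        f"{seen[arm.name]!r} and {pre.id!r}"
                    )
                seen[arm.name] = pre.id
        if set(seen) != set(self.arms_by_name):
            raise ReferenceLoadError("arms_by_name index out of sync with precursors")


def build_reference(
    sequences: Mapping[str, str],
    coords: Iterable[tuple[str, str, int, int, str]],
) -> ReferenceSet:
    """Assemble and validate a ReferenceSet from in-memory parts.

    ``coords`` rows are (precursor_id, mature_name, start, end, arm) with
    0-based half-open coordinates.
    """
    precursors = {
        pid: Precursor(id=pid, sequence=seq) for pid, seq in sequences.items()
    }
    arms_by_name: dict[str, ReferenceMiR] = {}
    for row_no, (pid, name, start, end, arm_label) in enumerate(coords, start=1):
        if pid not in precursors:
            raise ReferenceLoadError(
                f"coords row {row_no}: unknown precursor id {pid!r}"
            )
        pre = precursors[pid]
        start, end = int(start), int(end)
        if not (0 <= start < end <= len(pre.sequence)):
            raise ReferenceLoadError(
                f"coords row {row_no} ({name!r}): coordinates out of bounds "
                f"[{start}, {end}) on {len(pre.sequence)}-nt precursor {pid!r}"
            )
        if name in arms_by_name:
            raise ReferenceLoadError(
                f"coords row {row_no}: duplicate mature name {name!r}"
            )
        ref = ReferenceMiR(
            name=name,
            precursor_id=pid,
            start=start,
            end=end,
            arm=arm_label,
            sequence=pre.sequence[start:end],
        )
        pre.arms.append(ref)
        arms_by_name[name] = ref
    refset = ReferenceSet(precursors=precursors, arms_by_name=arms_by_name)
    refset.validate()
    return refset


def load_reference(hairpin_fasta: str | Path, coords_table: str | Path) -> ReferenceSet:
    """Load precursor FASTA + arm coordinate TSV into a validated ReferenceSet."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(hairpin_fasta), "fasta"):
        if record.id in sequences:
            raise ReferenceLoadError(f"duplicate precursor id {record.id!r} in FASTA")
        sequences[record.id] = normalize_rna(
            str(record.seq), where=f"precursor {record.id!r}"
        )
    coords = _read_coords(coords_table)
    return build_reference(sequences, coords)


def _read_coords(path: str | Path) -> list[tuple[str, str, int, int, str]]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or [c for c in COORDS_COLUMNS if c not in reader.fieldnames]:
            raise ReferenceLoadError(
                f"coords table {path}: header must contain columns {COORDS_COLUMNS}"
            )
        rows = []
        for i, row in enumerate(reader, start=2):
            try:
                rows.append(
                    (
                        row["precursor_id"],
                        row["mature_name"],
                        int(row["start"]),
                        int(row["end"]),
                        row["arm"],
                    )
                )
            except (TypeError, KeyError, ValueError) as exc:
                raise ReferenceLoadError(
                    f"coords table {path}: malformed line {i}: {exc}"
                ) from exc
    return rows


def write_reference(
    refset: ReferenceSet, hairpin_fasta: str | Path, coords_table: str | Path
) -> None:
    """Write the reference back to FASTA + coords TSV (round-trips bit-exactly)."""
    records = [
        SeqRecord(Seq(pre.sequence), id=pid, description="")
        for pid, pre in sorted(refset.precursors.items())
    ]
    SeqIO.write(records, str(hairpin_fasta), "fasta")
    with open(coords_table, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COORDS_COLUMNS)
        for pid, pre in sorted(refset.precursors.items()):
            for arm in sorted(pre.arms, key=lambda a: a.start):
                writer.writerow([pid, arm.name, arm.start, arm.end, arm.arm])


def gff3_to_coords(gff3_path: str | Path, out_tsv: str | Path | None = None) -> pd.DataFrame:
    """Convert a miRBase-style GFF3 annotation to the coords TSV dialect.

    Hairpins are ``miRNA_primary_transcript`` features; matures are ``miRNA``
    features linked by ``Derives_from``.  Genomic 1-based inclusive intervals
    are converted to precursor-local 0-based half-open coordinates, strand
    aware.  The arm label is taken from a ``-5p``/``-3p`` name suffix, or
    inferred from the position within the hairpin otherwise.
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attr"]
    df = pd.read_csv(
        gff3_path, sep="\t", comment="#", names=cols, header=None, dtype={"attr": str}
    )

    def attrs(s: str) -> dict[str, str]:
        return dict(kv.split("=", 1) for kv in s.strip().split(";") if "=" in kv)

    primaries: dict[str, dict] = {}
    for _, row in df[df["type"] == "miRNA_primary_transcript"].iterrows():
        a = attrs(row["attr"])
        primaries[a["ID"]] = {
            "name": a.get("Name", a["ID"]),
            "start": int(row["start"]),
            "end": int(row["end"]),
            "strand": row["strand"],
        }
    out_rows = []
    for _, row in df[df["type"] == "miRNA"].iterrows():
        a = attrs(row["attr"])
        parent_id = a.get("Derives_from")
        if parent_id is None or parent_id not in primaries:
            raise ReferenceLoadError(
                f"GFF3 mature {a.get('Name', a.get('ID'))!r}: missing or unknown Derives_from"
            )
        pre = primaries[parent_id]
        m_start, m_end = int(row["start"]), int(row["end"])
        if pre["strand"] == "-":
            local_start = pre["end"] - m_end
            local_end = pre["end"] - m_start + 1
        else:
            local_start = m_start - pre["start"]
            local_end = m_end - pre["start"] + 1
        name = a.get("Name", a["ID"])
        pre_len = pre["end"] - pre["start"] + 1
        if name.endswith("-5p"):
            arm = "5p"
        elif name.endswith("-3p"):
            arm = "3p"
        else:
            arm = "5p" if local_start < pre_len - local_end else "3p"
        out_rows.append((pre["name"], name, local_start, local_end, arm))
    result = pd.DataFrame(out_rows, columns=COORDS_COLUMNS).sort_values(
        ["precursor_id", "start"], kind="mergesort"
    )
    if out_tsv is not None:
        result.to_csv(out_tsv, sep="\t", index=False)
    return result.reset_index(drop=True)


def fixture_reference() -> ReferenceSet:
    """A small deterministic reference of well-known human mature arms.

    Each arm is embedded in a synthetic precursor with 4-nt G/C-only flanks,
    so that A/U tails on reads can never be accidentally templated by the
    flanking sequence.
    """
    from .fixtures import FIXTURE_ARMS

    flank5, flank3 = "GGCG", "CGCC"
    sequences: dict[str, str] = {}
    coords: list[tuple[str, str, int, int, str]] = []
    for name, (arm_label, arm_seq) in sorted(FIXTURE_ARMS.items()):
        pid = "pre-" + name.rsplit("-", 1)[0]
        sequences[pid] = flank5 + arm_seq + flank3
        coords.append((pid, name, len(flank5), len(flank5) + len(arm_seq), arm_label))
    return build_reference(sequences, coords)
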