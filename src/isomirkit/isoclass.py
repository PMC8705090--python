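"""isomiR classification of small-RNA reads against mature-arm references.

A read is explained as a contiguous, exact ("templated") match to a
precursor hairpin, starting near a mature arm's 5' end and ending near its
3' end, optionally followed by a short non-templated 3' tail.  End offsets
are measured in precursor coordinates:

* ``offset5`` = read 5' start - arm 5' start (positive = 5'-trimmed),
* ``offset3`` = read 3' end (tail included) - arm 3' end (positive = longer).

Categories: ``refseq`` (identical to the arm), ``iso5``/``iso3``/``iso5_3``
(templated variants by which end is offset), and ``nontemplate`` (any variant
carrying a non-templated 3' tail).  The templated match is always maximal:
a tail is declared only once the precursor stops agreeing with the read, so
the first tail base never re-matches the hairpin (except at the precursor's
very end).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .refdb import RNA_ALPHABET, ReferenceSet

logger = logging.getLogger(__name__)

CATEGORIES = ("refseq", "iso5", "iso3", "iso5_3", "nontemplate")

#: reason codes for unassigned reads
REASON_LENGTH = "length"
REASON_TAIL_TOO_LONG = "tail_too_long"
REASON_NO_MATCH = "no_match"


class NameParseError(ValueError):
    """Raised on a malformed canonical isomiR name."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None else f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class ClassifierConfig:
    """End-offset and tail windows for the classifier.

    ``max_offset`` bounds |offset5| and the templated part of the 3'
    displacement separately; the tail adds at most ``max_tail`` further
    nucleotides, so |offset3| can reach ``max_offset + max_tail``.
    """

    max_offset: int = 5
    max_tail: int = 3
    min_read_len: int = 16
    max_read_len: int = 28

    def __post_init__(self) -> None:
        if min(self.max_offset, self.max_tail, self.min_read_len, self.max_read_len) <= 0:
            raise ValueError("all ClassifierConfig fields must be positive")
        if self.min_read_len > self.max_read_len:
            raise ValueError("min_read_len must not exceed max_read_len")


def _fmt_offset(o: int) -> str:
    return f"+{o}" if o > 0 else str(o)


@dataclass(frozen=True)
class IsoMiRCall:
    """One classified read: parent arm, category, end offsets, tail."""

    parent: str
    category: str
    offset5: int
    offset3: int
    tail: str
    read_sequence: str

    @property
    def name(self) -> str:
        return name_call(self)


@dataclass(frozen=True)
class Unassigned:
    """A read no arm can explain within the configured windows."""

    read_sequence: str
    reason: str


def _category(offset5: int, offset3: int, tail: str) -> str:
    if tail:
        return "nontemplate"
    if offset5 == 0 and offset3 == 0:
        return "refseq"
    if offset3 == 0:
        return "iso5"
    if offset5 == 0:
        return "iso3"
    return "iso5_3"


def classify_read(
    read: str, refset: ReferenceSet, config: ClassifierConfig = ClassifierConfig()
) -> IsoMiRCall | Unassigned:
    """Classify one read against every arm of the reference.

    Candidate explanations are enumerated over all arms and all 5' start
    positions within ``max_offset`` of an arm start; for each start the
    templated match is extended maximally and the remaining suffix becomes
    the tail.  Ambiguity is resolved deterministically: longest templated
    match, then smallest |offset5|+|offset3|, then shortest tail, then
    lexicographically smallest parent name (with the offset/tail tuple as a
    final total-order tie-break).  The read is counted once, never
    fractionally.
    """
    read = read.strip().upper().replace("T", "U")
    bad = set(read) - RNA_ALPHABET
    if bad:
        raise ValueError(f"read contains non-RNA characters {sorted(bad)!r}")
    if not (config.min_read_len <= len(read) <= config.max_read_len):
        return Unassigned(read_sequence=read, reason=REASON_LENGTH)

    best_key: tuple | None = None
    best_call: IsoMiRCall | None = None
    saw_tail_too_long = False

    for name, arm in refset.arms_by_name.items():
        pre_seq = refset.precursors[arm.precursor_id].sequence
        s, e = arm.start, arm.end
        lo = max(0, s - config.max_offset)
        hi = min(len(pre_seq) - 1, s + config.max_offset)
        for p in range(lo, hi + 1):
            # maximal contiguous exact match of the read prefix at p
            matched = 0
            while (
                matched < len(read)
                and p + matched < len(pre_seq)
                and read[matched] == pre_seq[p + matched]
            ):
                matched += 1
            if matched == 0:
                continue
            templated_end = p + matched
            offset3_templated = templated_end - e
            if abs(offset3_templated) > config.max_offset:
                continue
            tail = read[matched:]
            if len(tail) > config.max_tail:
                saw_tail_too_long = True
                continue
            offset5 = p - s
            offset3 = offset3_templated + len(tail)
            key = (
                -matched,
                abs(offset5) + abs(offset3),
                len(tail),
                name,
                offset5,
                offset3,
                tail,
            )
            if best_key is None or key < best_key:
                best_key = key
                best_call = IsoMiRCall(
                    parent=name,
                    category=_category(offset5, offset3, tail),
                    offset5=offset5,
                    offset3=offset3,
                    tail=tail,
                    read_sequence=read,
                )
    if best_call is not None:
        return best_call
    return Unassigned(
        read_sequence=read,
        reason=REASON_TAIL_TOO_LONG if saw_tail_too_long else REASON_NO_MATCH,
    )


def name_call(call: IsoMiRCall) -> str:
    """Canonical name: parent for refseq, ``_t_{o5}_{o3}`` for templated
    variants, ``_nont_{o5}_{o3}_{tail}`` for non-templated additions."""
    if call.category == "refseq":
        return call.parent
    o5, o3 = _fmt_offset(call.offset5), _fmt_offset(call.offset3)
    if call.category == "nontemplate":
        return f"{call.parent}_nont_{o5}_{o3}_{call.tail}"
    return f"{call.parent}_t_{o5}_{o3}"


@dataclass(frozen=True)
class ParsedName:
    parent: str
    category: str
    offset5: int
    offset3: int
    tail: str


_NAME_RE = re.compile(
    r"^(?P<parent>.+?)_(?P<kind>[A-Za-z]+)_(?P<o5>0|[+-][1-9]\d*)_(?P<o3>0|[+-][1-9]\d*)"
    r"(?:_(?P<tail>[A-Z]+))?$"
)


def parse_name(name: str) -> ParsedName:
    """Invert :func:`name_call`; a bare (suffix-free) name is a refseq miR."""
    m = _NAME_RE.match(name)
    if m is None:
        # No offset suffix grammar present: the whole string is a parent name,
        # unless it looks like a failed attempt at the suffix grammar.
        if re.search(r"_(t|nont)_", name):
            raise NameParseError(
                f"malformed isomiR name {name!r}", name.find("_")
            )
        return ParsedName(parent=name, category="refseq", offset5=0, offset3=0, tail="")
    kind = m.group("kind")
    if kind not in ("t", "nont"):
        raise NameParseError(
            f"unknown type token {kind!r} in {name!r}", m.start("kind")
        )
    offset5, offset3 = int(m.group("o5")), int(m.group("o3"))
    tail = m.group("tail")
    if kind == "t":
        if tail is not None:
            raise NameParseError(
                f"templated name {name!r} carries a tail", m.start("tail")
            )
        if offset5 == 0 and offset3 == 0:
            raise NameParseError(
                f"templated name {name!r} with zero offsets; refseq names are unadorned",
                m.start("kind"),
            )
        tail = ""
    else:
        if not tail:
            raise NameParseError(f"non-template name {name!r} lacks a tail", len(name))
        bad = set(tail) - RNA_ALPHABET
        if bad:
            raise NameParseError(
                f"tail of {name!r} contains non-RNA characters {sorted(bad)!r}",
                m.start("tail"),
            )
    return ParsedName(
        parent=m.group("parent"),
        category=_category(offset5, offset3, tail),
        offset5=offset5,
        offset3=offset3,
        tail=tail,
    )


def seed_of(sequence: str) -> str:
    """Seed region: nucleotides 2-8 (1-based, inclusive) of a mature sequence."""
    if len(sequence) < 8:
        raise ValueError(f"sequence of length {len(sequence)} has no full seed (need >= 8)")
    return sequence[1:8]


def is_seed_shifted(call: IsoMiRCall | ParsedName | str) -> bool:
    """Whether the variant's seed differs from its parent's (any 5' offset)."""
    if isinstance(call, str):
        call = parse_name(call)
    return call.offset5 != 0


class FastqError(ValueError):
    """Raised on an unreadable or truncated FASTQ input."""


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _count_fastq(path: str | Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    n = 0
    try:
        with _open_text(path) as handle:
            for record in SeqIO.parse(handle, "fastq"):
                seq = str(record.seq).upper().replace("T", "U")
                counts[seq] = counts.get(seq, 0) + 1
                n += 1
    except (ValueError, OSError) as exc:
        raise FastqError(f"{path}: record {n + 1}: {exc}") from exc
    if n == 0:
        logger.warning("FASTQ %s contains no reads", path)
    return counts


def quantify(
    samples: Mapping[str, str | Path] | Sequence[tuple[str, str | Path]],
    refset: ReferenceSet,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse, classify, and tally reads per sample.

    Returns ``(counts, unassigned)``: a features x samples integer matrix
    keyed by canonical isomiR names, and a per-sample per-reason tally of
    unassigned reads.  Identical read sequences are collapsed before
    classification and contribute their copy number to exactly one name.
    """
    items = list(samples.items()) if isinstance(samples, Mapping) else list(samples)
    names = [s for s, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("sample names must be unique")

    cache: dict[str, IsoMiRCall | Unassigned] = {}
    per_sample: dict[str, dict[str, int]] = {}
    unassigned_rows: list[tuple[str, str, int]] = []
    for sample, path in items:
        seq_counts = _count_fastq(path)
        tallies: dict[str, int] = {}
        missed: dict[str, int] = {}
        for seq, copies in seq_counts.items():
            result = cache.get(seq)
            if result is None:
                result = cache[seq] = classify_read(seq, refset, config)
            if isinstance(result, Unassigned):
                missed[result.reason] = missed.get(result.reason, 0) + copies
            else:
                feat = result.name
                tallies[feat] = tallies.get(feat, 0) + copies
        per_sample[sample] = tallies
        unassigned_rows.extend((sample, reason, n) for reason, n in sorted(missed.items()))
        logger.info(
            "classify: sample %s: %d reads -> %d features, %d unassigned",
            sample, sum(seq_counts.values()), len(tallies), sum(missed.values()),
        )

    features = sorted({f for t in per_sample.values() for f in t})
    counts = pd.DataFrame(
        {s: [per_sample[s].get(f, 0) for f in features] for s in names},
        index=pd.Index(features, name="feature"),
        dtype="int64",
    )
    unassigned = pd.DataFrame(unassigned_rows, columns=["sample", "reason", "count"])
    return counts, unassigned


def type_distribution(
    matrix: pd.DataFrame, feature_subset: Iterable[str] | None = None
) -> pd.Series:
    """Percentage of distinct features per isomiR category.

    Accounting is per sequence class (each feature name counts once),
    not per read, so the distribution describes the variant repertoire.
    """
    features = list(feature_subset) if feature_subset is not None else list(matrix.index)
    if not features:
        raise ValueError("empty feature subset")
    tally = dict.fromkeys(CATEGORIES, 0)
    for feat in features:
        tally[parse_name(feat).category] += 1
    return pd.Series(
        {cat: 100.0 * n / len(features) for cat, n in tally.items()}, name="percent"
    )


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a count matrix as TSV with a leading ``feature`` column."""
    out = matrix.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (featureCounts-like) count matrix."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "feature"
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate feature or sample names")
    if (matrix < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return matrix.astype("int64")


def write_unassigned(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
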