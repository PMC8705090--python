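"""Shared fixtures and the brute-force classification oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from isomirkit import ClassifierConfig, IsoMiRCall, Unassigned, fixture_reference
from isomirkit.refdb import ReferenceSet, build_reference

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refset() -> ReferenceSet:
    return fixture_reference()


def oracle_classify(
    read: str, refset: ReferenceSet, config: ClassifierConfig = ClassifierConfig()
) -> IsoMiRCall | Unassigned:
    """Brute-force enumeration oracle for read classification.

    Enumerates every (arm, start, templated-length, tail) split by direct
    string slicing, applies the window constraints and the maximality rule
    (the first tail base must not be templated unless the match reaches the
    precursor end), and picks the winner by the documented tie-break.
    Independent of the walking implementation in ``isomirkit.isoclass``.
    """
    if not (config.min_read_len <= len(read) <= config.max_read_len):
        return Unassigned(read_sequence=read, reason="length")
    best_key = None
    best = None
    saw_tail_too_long = False
    for name, arm in refset.arms_by_name.items():
        pre = refset.precursors[arm.precursor_id].sequence
        s, e = arm.start, arm.end
        for p in range(len(pre)):
            if abs(p - s) > config.max_offset:
                continue
            for matched in range(1, len(read) + 1):
                if p + matched > len(pre) or pre[p:p + matched] != read[:matched]:
                    continue
                tail = read[matched:]
                if tail and p + matched < len(pre) and pre[p + matched] == tail[0]:
                    continue  # tail base would be templated: not maximal
                o3t = (p + matched) - e
                if abs(o3t) > config.max_offset:
                    continue
                if len(tail) > config.max_tail:
                    saw_tail_too_long = True
                    continue
                o5, o3 = p - s, o3t + len(tail)
                key = (-matched, abs(o5) + abs(o3), len(tail), name, o5, o3, tail)
                if best_key is None or key < best_key:
                    best_key = key
                    if tail:
                        category = "nontemplate"
                    elif o5 == 0 and o3 == 0:
                        category = "refseq"
                    elif o3 == 0:
                        category = "iso5"
                    elif o5 == 0:
                        category = "iso3"
                    else:
                        category = "iso5_3"
                    best = IsoMiRCall(
                        parent=name, category=category, offset5=o5, offset3=o3,
                        tail=tail, read_sequence=read,
                    )
    if best is not None:
        return best
    return Unassigned(
        read_sequence=read,
        reason="tail_too_long" if saw_tail_too_long else "no_match",
    )


def random_instances(seed: int, n: int):
    """Yield (read, single-precursor ReferenceSet) pairs for oracle checks.

    Half the reads are perturbed arm-derived sequences (random end offsets,
    tails, occasional point changes), half are unrelated random strings, so
    both assigned and unassigned outcomes are exercised.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))

    def rand_rna(k: int) -> str:
        return "".join(rng.choice(bases, size=k))

    for i in range(n):
        flank5, flank3 = rand_rna(int(rng.integers(4, 9))), rand_rna(int(rng.integers(4, 9)))
        arm_len = int(rng.integers(19, 26))
        arm_seq = rand_rna(arm_len)
        pre = flank5 + arm_seq + flank3
        s = len(flank5)
        single = build_reference(
            {"pre-x": pre}, [("pre-x", "syn-x-5p", s, s + arm_len, "5p")]
        )
        if i % 2 == 0:
            o5 = int(rng.integers(-6, 7))
            o3t = int(rng.integers(-6, 7))
            start, end = s + o5, s + arm_len + o3t
            if not (0 <= start < end <= len(pre)):
                read = rand_rna(int(rng.integers(16, 29)))
            else:
                read = pre[start:end] + rand_rna(int(rng.integers(0, 5)))
                if rng.random() < 0.2 and read:
                    pos = int(rng.integers(0, len(read)))
                    read = read[:pos] + str(rng.choice(bases)) + read[pos + 1:]
        else:
            read = rand_rna(int(rng.integers(16, 29)))
        yield read, single
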