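"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates a grouped small-RNA study: random precursor hairpins
with mature arms, per-arm isomiR composition (end offsets and A/U-heavy
non-templated tails), negative-binomial copy numbers with planted log2 fold
changes between groups, and a matching gene-count matrix with planted
anti-correlated (regulator, gene) target pairs plus a TF regulation table
containing a plantable TF -> miR-family -> TF-gene motif.

Every output is a pure function of the configuration and its seed, and a
truth table records the exact planted counts, fold changes, and pairs so
each pipeline stage can be tested against known ground truth.  Counts are
drawn as NB(mean, dispersion) with variance ``mean + dispersion * mean**2``;
with ``dispersion == 0`` counts are ``round(mean)`` exactly (deterministic),
which makes quantification exactly reproducible from the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .diffexp import Design
from .isoclass import ClassifierConfig, IsoMiRCall, Unassigned, classify_read, name_call, _category
from .refdb import ReferenceSet, build_reference, write_reference

#: default per-arm isomiR composition: (offset5, templated offset3, tail) -> weight.
#: Adenine-heavy tails; all offsets well inside the default classifier windows.
DEFAULT_ISOFORMS: dict[tuple[int, int, str], float] = {
    (0, 0, ""): 0.40,     # reference sequence
    (1, 0, ""): 0.10,     # 5'-trimmed (seed-shifting)
    (0, -1, ""): 0.15,    # 3'-trimmed
    (0, 1, ""): 0.08,     # 3'-extended (templated)
    (1, -1, ""): 0.07,    # both ends
    (0, 0, "A"): 0.10,
    (0, 0, "AA"): 0.04,
    (0, 0, "AAA"): 0.02,
    (0, 0, "U"): 0.03,
    (0, -1, "AU"): 0.01,
}


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.  The seed is mandatory."""

    rng_seed: int
    n_precursors: int = 8
    arm_len_range: tuple[int, int] = (19, 25)
    flank_range: tuple[int, int] = (4, 8)
    groups: tuple[str, ...] = ("P", "hCG+9")  # first group is the reference
    n_samples_per_group: int = 6
    base_mean: float = 300.0          # mean copies per arm per sample
    planted_lfc_magnitude: float = 2.5
    planted_arm_fraction: float = 0.5
    nb_dispersion: float = 0.1
    n_genes: int = 200
    gene_base_mean: float = 500.0
    gene_lfc_magnitude: float = 2.5
    n_planted_pairs: int = 8

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise SyntheticError("rng_seed is mandatory")
        if len(self.groups) < 2:
            raise SyntheticError("need a reference group and at least one test group")
        if min(self.n_precursors, self.n_samples_per_group, self.n_genes) <= 0:
            raise SyntheticError("all counts must be positive")


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def make_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> ReferenceSet:
    """Random precursors with one or two non-overlapping arms.

    The precursor base immediately 3' of every arm is drawn from {G, C}, so
    the default A/U tails can never be accidentally templated.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.arm_len_range
    flo, fhi = config.flank_range
    sequences: dict[str, str] = {}
    coords: list[tuple[str, str, int, int, str]] = []
    for i in range(config.n_precursors):
        pid = f"syn-mir-{i + 1}"
        two_arms = i % 3 != 2  # every third precursor carries a single arm
        flank5 = _random_rna(rng, int(rng.integers(flo, fhi + 1)))
        arm5 = _random_rna(rng, int(rng.integers(lo, hi + 1)))
        if two_arms:
            loop = _random_rna(rng, int(rng.integers(8, 13)))
            arm3 = _random_rna(rng, int(rng.integers(lo, hi + 1)))
        else:
            loop, arm3 = "", ""
        flank3 = _random_rna(rng, int(rng.integers(flo, fhi + 1)))
        guard = lambda: str(rng.choice(["G", "C"]))
        if loop:
            loop = guard() + loop[1:]
        else:
            flank3 = guard() + flank3[1:]
        seq = flank5 + arm5 + loop + arm3 + flank3
        if two_arms:
            # guard base directly after the 3p arm
            pos = len(flank5) + len(arm5) + len(loop) + len(arm3)
            seq = seq[:pos] + guard() + seq[pos + 1:]
        sequences[pid] = seq
        s5 = len(flank5)
        coords.append((pid, f"syn-miR-{i + 1}-5p", s5, s5 + len(arm5), "5p"))
        if two_arms:
            s3 = len(flank5) + len(arm5) + len(loop)
            coords.append((pid, f"syn-miR-{i + 1}-3p", s3, s3 + len(arm3), "3p"))
    return build_reference(sequences, coords)


def read_for(
    refset: ReferenceSet, arm_name: str, offset5: int, offset3_templated: int, tail: str
) -> str:
    """The exact read sequence implied by (arm, end offsets, tail)."""
    arm = refset.arm(arm_name)
    pre = refset.precursor_of(arm)
    start = arm.start + offset5
    end = arm.end + offset3_templated
    if not (0 <= start < end <= len(pre.sequence)):
        raise SyntheticError(
            f"isoform ({offset5}, {offset3_templated}) of {arm_name!r} leaves the precursor"
        )
    return pre.sequence[start:end] + tail


@dataclass(frozen=True)
class IsoProfile:
    """Per-arm relative abundances of isoforms (weights sum to 1 per arm)."""

    arms: Mapping[str, Mapping[tuple[int, int, str], float]]

    def __post_init__(self) -> None:
        for arm, isoforms in self.arms.items():
            if not isoforms:
                raise SyntheticError(f"arm {arm!r}: empty isoform profile")
            total = sum(isoforms.values())
            if abs(total - 1.0) > 1e-9 or min(isoforms.values()) < 0:
                raise SyntheticError(
                    f"arm {arm!r}: abundances must be >= 0 and sum to 1 (got {total})"
                )

    @classmethod
    def default(
        cls,
        refset: ReferenceSet,
        isoforms: Mapping[tuple[int, int, str], float] = None,
        classifier_config: ClassifierConfig = ClassifierConfig(),
    ) -> "IsoProfile":
        """Build the default profile for every arm of ``refset``.

        Each candidate isoform is verified by classifying its realized read
        under ``classifier_config``; isoforms whose read would classify to a
        different name (e.g. a tail base re-matching the hairpin after a 3'
        trim, or an ambiguous duplicate sequence) are dropped and the
        remaining weights renormalized.  This guarantees that every planted
        read is classifiable back to its planted name.
        """
        isoforms = dict(DEFAULT_ISOFORMS if isoforms is None else isoforms)
        arms: dict[str, dict[tuple[int, int, str], float]] = {}
        for arm_name in sorted(refset.arms_by_name):
            kept: dict[tuple[int, int, str], float] = {}
            for (o5, o3t, tail), weight in isoforms.items():
                try:
                    seq = read_for(refset, arm_name, o5, o3t, tail)
                except SyntheticError:
                    continue
                if not (
                    classifier_config.min_read_len
                    <= len(seq)
                    <= classifier_config.max_read_len
                ):
                    continue
                call = classify_read(seq, refset, classifier_config)
                if isinstance(call, Unassigned):
                    continue
                if (
                    call.parent == arm_name
                    and call.offset5 == o5
                    and call.offset3 == o3t + len(tail)
                    and call.tail == tail
                ):
                    kept[(o5, o3t, tail)] = weight
            if not kept:
                raise SyntheticError(f"arm {arm_name!r}: no unambiguous isoform")
            total = sum(kept.values())
            arms[arm_name] = {k: w / total for k, w in kept.items()}
        return cls(arms=arms)


def planted_arm_lfcs(refset: ReferenceSet, config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Assign planted log2 fold changes to a random subset of arms.

    Half the planted arms go up and half down by ``planted_lfc_magnitude``;
    the rest are null.
    """
    arm_names = sorted(refset.arms_by_name)
    n_planted = max(2, int(round(config.planted_arm_fraction * len(arm_names))))
    chosen = list(rng.permutation(arm_names)[:n_planted])
    lfcs = pd.Series(0.0, index=pd.Index(arm_names, name="arm"))
    for j, arm in enumerate(sorted(chosen)):
        lfcs.loc[arm] = config.planted_lfc_magnitude * (1 if j % 2 == 0 else -1)
    return lfcs


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(round(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


@dataclass
class ReadSim:
    """FASTQ files plus the exact planted truth."""

    fastqs: dict[str, Path]           # sample -> path
    design: Design
    truth_counts: pd.DataFrame        # features x samples planted copy numbers
    feature_lfc: pd.Series            # canonical name -> planted log2fc
    arm_lfc: pd.Series


def simulate_reads(
    refset: ReferenceSet,
    profile: IsoProfile,
    config: SimConfig,
    outdir: str | Path,
    rng: np.random.Generator | None = None,
    arm_lfc: pd.Series | None = None,
) -> ReadSim:
    """Emit per-sample FASTQ libraries realizing the profile, plus truth."""
    unknown = set(profile.arms) - set(refset.arms_by_name)
    if unknown:
        raise SyntheticError(f"profile references unknown arms {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if arm_lfc is None:
        arm_lfc = planted_arm_lfcs(refset, config, rng)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    feature_names: dict[tuple[str, tuple[int, int, str]], str] = {}
    feature_seq: dict[str, str] = {}
    feature_lfc: dict[str, float] = {}
    for arm_name, isoforms in sorted(profile.arms.items()):
        for (o5, o3t, tail) in sorted(isoforms):
            o3 = o3t + len(tail)
            call = IsoMiRCall(
                parent=arm_name,
                category=_category(o5, o3, tail),
                offset5=o5,
                offset3=o3,
                tail=tail,
                read_sequence="",
            )
            feat = name_call(call)
            feature_names[(arm_name, (o5, o3t, tail))] = feat
            feature_seq[feat] = read_for(refset, arm_name, o5, o3t, tail)
            feature_lfc[feat] = float(arm_lfc.get(arm_name, 0.0))

    ref_group = config.groups[0]
    samples: dict[str, str] = {}
    for group in config.groups:
        for j in range(config.n_samples_per_group):
            samples[f"{group}_r{j + 1}"] = group
    features = sorted(feature_seq)
    truth = pd.DataFrame(
        0, index=pd.Index(features, name="feature"), columns=list(samples), dtype="int64"
    )
    fastqs: dict[str, Path] = {}
    for sample, group in samples.items():
        path = outdir / f"{sample}.fastq"
        serial = 0
        with open(path, "w") as handle:
            for arm_name, isoforms in sorted(profile.arms.items()):
                lfc = float(arm_lfc.get(arm_name, 0.0))
                arm_mean = config.base_mean * (2.0 ** lfc if group != ref_group else 1.0)
                for iso_key in sorted(isoforms):
                    feat = feature_names[(arm_name, iso_key)]
                    copies = _nb_draw(rng, isoforms[iso_key] * arm_mean, config.nb_dispersion)
                    truth.loc[feat, sample] = copies
                    seq = feature_seq[feat]
                    qual = "I" * len(seq)
                    for _ in range(copies):
                        serial += 1
                        handle.write(f"@{sample}.r{serial:07d}\n{seq}\n+\n{qual}\n")
        fastqs[sample] = path

    design = Design(groups=samples, contrast=(config.groups[-1], ref_group))
    return ReadSim(
        fastqs=fastqs,
        design=design,
        truth_counts=truth,
        feature_lfc=pd.Series(feature_lfc, name="log2fc").sort_index(),
        arm_lfc=arm_lfc,
    )


@dataclass
class GeneSim:
    """Gene counts, target and TF tables, and the planted pair truth."""

    counts: pd.DataFrame
    targets: pd.DataFrame
    tf_table: pd.DataFrame
    design: Design
    gene_lfc: pd.Series
    planted_pairs: pd.DataFrame       # regulator, gene, expected klass
    tf_genes: list[str]
    motif: tuple[str, str, str]       # (TF_a, family feature, TF_b) planted path


def simulate_gene_counts(
    config: SimConfig,
    mir_feature_lfc: pd.Series,
    rng: np.random.Generator,
) -> GeneSim:
    """Gene matrix with planted anti-correlated targets and a TF motif.

    Each planted (regulator, gene) pair gives the gene a log2 fold change of
    opposite sign to its regulator's, a target-table row with score >= 80,
    and a same-regulator decoy row with score < 80 that must never pair.
    Two DE transcription-factor genes are planted in a
    regulator-up -> TF_a-down, TF_a -> family_b, family_b-down -> TF_b-up
    motif so circuit assembly can be checked end to end.
    """
    de_feats = mir_feature_lfc[mir_feature_lfc != 0.0]
    up = sorted(de_feats[de_feats > 0].index)
    down = sorted(de_feats[de_feats < 0].index)
    if not up or not down:
        raise SyntheticError("need planted regulators in both directions")

    # one representative feature per arm, favoring the reference isoform
    from .isoclass import parse_name

    def representatives(names: list[str]) -> list[str]:
        by_arm: dict[str, str] = {}
        for n in names:
            parsed = parse_name(n)
            if parsed.parent not in by_arm or parsed.category == "refseq":
                by_arm[parsed.parent] = n
        return sorted(by_arm.values())

    reps = representatives(up) + representatives(down)
    k = min(config.n_planted_pairs, len(reps))
    regulators = sorted(rng.permutation(reps)[:k])

    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    tf_a, tf_b = "TFA", "TFB"
    all_genes = genes + [tf_a, tf_b]
    gene_lfc = pd.Series(0.0, index=pd.Index(all_genes, name="gene"))

    target_rows: list[tuple[str, str, float]] = []
    pair_rows: list[tuple[str, str, str]] = []
    for i, reg in enumerate(regulators):
        gene = genes[i]
        sign = -np.sign(mir_feature_lfc.loc[reg])
        gene_lfc.loc[gene] = sign * config.gene_lfc_magnitude
        target_rows.append((reg, gene, float(rng.uniform(85, 99))))
        pair_rows.append((reg, gene, "negative"))
        # decoy below the score threshold: same regulator, another DE gene
        decoy_gene = genes[(i + 1) % k]
        target_rows.append((reg, decoy_gene, float(rng.uniform(50, 79))))
    # high-score rows onto null genes: prediction without differential expression
    for i, reg in enumerate(regulators):
        target_rows.append((reg, genes[k + i], float(rng.uniform(80, 99))))

    # TF motif: up-regulator -> TFA (down); TFA regulates family of a down
    # feature; that feature -> TFB (up); TFB regulates some family too.
    reg_up = representatives(up)[0]
    feat_down = representatives(down)[0]
    gene_lfc.loc[tf_a] = -config.gene_lfc_magnitude
    gene_lfc.loc[tf_b] = config.gene_lfc_magnitude
    target_rows.append((reg_up, tf_a, float(rng.uniform(90, 99))))
    pair_rows.append((reg_up, tf_a, "negative"))
    target_rows.append((feat_down, tf_b, float(rng.uniform(90, 99))))
    pair_rows.append((feat_down, tf_b, "negative"))

    from .integration import family_of

    tf_table = pd.DataFrame(
        [
            (tf_a, family_of(feat_down), "activate", True),
            (tf_b, family_of(reg_up), "activate", True),
            (tf_a, family_of(reg_up), "activate", False),  # non-curated: ignored
        ],
        columns=["tf", "mir_family", "direction", "literature_curated"],
    )

    ref_group = config.groups[0]
    samples = {
        f"{g}_r{j + 1}": g
        for g in config.groups
        for j in range(config.n_samples_per_group)
    }
    counts = pd.DataFrame(
        0, index=pd.Index(all_genes, name="feature"), columns=list(samples), dtype="int64"
    )
    for sample, group in samples.items():
        for gene in all_genes:
            mean = config.gene_base_mean * (
                2.0 ** gene_lfc.loc[gene] if group != ref_group else 1.0
            )
            counts.loc[gene, sample] = _nb_draw(rng, mean, config.nb_dispersion)

    design = Design(groups=samples, contrast=(config.groups[-1], ref_group))
    return GeneSim(
        counts=counts,
        targets=pd.DataFrame(target_rows, columns=["regulator", "gene", "score"]),
        tf_table=tf_table,
        design=design,
        gene_lfc=gene_lfc,
        planted_pairs=pd.DataFrame(pair_rows, columns=["regulator", "gene", "klass"]),
        tf_genes=[tf_a, tf_b],
        motif=(tf_a, feat_down, tf_b),
    )


@dataclass
class SimulatedStudy:
    """All generated inputs plus truth, in memory and on disk."""

    refset: ReferenceSet
    profile: IsoProfile
    reads: ReadSim
    genes: GeneSim
    paths: dict[str, Path]


def simulate_study(config: SimConfig, outdir: str | Path) -> SimulatedStudy:
    """Generate a complete synthetic study under ``outdir``.

    Writes the reference (FASTA + coords TSV), per-sample FASTQs with a
    manifest, the gene count matrix, target and TF tables, the design
    table, and the truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    refset = make_reference(config, rng)
    profile = IsoProfile.default(refset)
    reads = simulate_reads(refset, profile, config, outdir / "fastq", rng)
    genes = simulate_gene_counts(config, reads.feature_lfc, rng)

    paths: dict[str, Path] = {
        "hairpin_fasta": outdir / "reference.fasta",
        "coords": outdir / "coords.tsv",
        "manifest": outdir / "manifest.tsv",
        "design": outdir / "design.tsv",
        "gene_counts": outdir / "gene_counts.tsv",
        "targets": outdir / "targets.tsv",
        "tf_table": outdir / "tf_table.tsv",
        "truth_counts": outdir / "truth_counts.tsv",
        "truth_mir_lfc": outdir / "truth_mir_lfc.tsv",
        "truth_gene_lfc": outdir / "truth_gene_lfc.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
    }
    write_reference(refset, paths["hairpin_fasta"], paths["coords"])
    manifest = pd.DataFrame(
        [
            (sample, str(path), reads.design.groups[sample])
            for sample, path in sorted(reads.fastqs.items())
        ],
        columns=["sample", "fastq", "group"],
    )
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    pd.DataFrame(
        sorted(reads.design.groups.items()), columns=["sample", "group"]
    ).to_csv(paths["design"], sep="\t", index=False)
    genes.counts.to_csv(paths["gene_counts"], sep="\t")
    genes.targets.to_csv(paths["targets"], sep="\t", index=False)
    genes.tf_table.to_csv(paths["tf_table"], sep="\t", index=False)
    reads.truth_counts.to_csv(paths["truth_counts"], sep="\t")
    reads.feature_lfc.rename_axis("feature").to_csv(paths["truth_mir_lfc"], sep="\t")
    genes.gene_lfc.rename_axis("gene").to_csv(paths["truth_gene_lfc"], sep="\t")
    genes.planted_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    return SimulatedStudy(refset=refset, profile=profile, reads=reads, genes=genes, paths=paths)
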