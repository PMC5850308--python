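"""Synthetic degraded small-RNA libraries with known ground truth.

The generator emulates the statistical structure of an archaeological
small-RNA experiment: one deeply sequenced ancient library whose reads are
dominated by rRNA breakdown products (≈71% of sRNA-sized reads vs ≈23% in
modern controls), enriched for sRNA-sized fragments (≈59% vs ≈17%), and
carrying strand-polarized C->T deamination; plus N multiplexed modern
control libraries sharing a heavy-tailed miRNA family baseline.  Three
fold-changes are planted on the ancient sample (two families up, one
down), giving every downstream stage a recoverable truth.

Counts per miRNA family follow a negative binomial parameterized by
(mean μ, variance r·μ), the same mean-variance relation the differential
statistics assume.  All randomness flows from one seed; identical configs
produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .pia import HitList, Taxonomy
from .references import ReferenceSet, reverse_complement

_BASES = np.array(list("ACGT"))

#: NextFlex-style small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: mRNA references always present: the miR159/miR319 target transcripts
TARGET_MRNAS = ("GAMYB", "PCF5", "PCF6")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Class fractions are fractions *of sRNA-sized reads* except
    ``srna_fraction_*`` which is the fraction of all reads whose insert
    falls in the 18-25 nt window.  ``mirna_fraction`` sets the expected
    miRNA share of sRNA-sized reads; in deep real libraries the share of
    total reads is far smaller, but at desk-scale depths a larger share
    keeps per-family counts informative (see the methods note).
    """

    seed: int = 0
    n_mirna_families: int = 23
    n_controls: int = 19
    reads_per_control: int = 30_000
    reads_ancient: int = 100_000
    srna_fraction_ancient: float = 0.59
    srna_fraction_modern: float = 0.17
    rrna_fraction_ancient: float = 0.71
    rrna_fraction_modern: float = 0.23
    retro_fraction_ancient: float = 0.0024
    retro_fraction_modern: float = 0.0112
    mirna_fraction: float = 0.08
    deamination_rate: float = 0.02
    overdispersion_r: float = 2.0
    planted_effects: dict[str, float] = field(
        default_factory=lambda: {"mir159": 4.0, "mir319": 4.0, "mir396": 0.25}
    )
    adapter_seq: str = DEFAULT_ADAPTER
    read_length: int = 50
    #: relative s.d. of within-sRNA class fractions across controls
    class_fraction_rel_sd: float = 0.10
    #: log-scale s.d. of baseline family abundances (~3 orders of magnitude)
    lognormal_sigma: float = 2.0
    #: ancient-sample weight ratio of PCF (5+6 combined) to GAMYB fragments
    target_ratio_ancient: float = 10.0

    def validate(self) -> None:
        if self.n_mirna_families < 4:
            raise ValueError("need >= 4 miRNA families (3 planted + baseline)")
        if self.reads_per_control <= 0 or self.reads_ancient <= 0:
            raise ValueError("read budgets must be positive")
        if self.n_controls <= 0:
            raise ValueError("need at least one control sample")
        for name in (
            "srna_fraction_ancient",
            "srna_fraction_modern",
            "rrna_fraction_ancient",
            "rrna_fraction_modern",
            "retro_fraction_ancient",
            "retro_fraction_modern",
            "mirna_fraction",
            "deamination_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for kind in ("ancient", "modern"):
            total = (
                getattr(self, f"rrna_fraction_{kind}")
                + getattr(self, f"retro_fraction_{kind}")
                + self.mirna_fraction
            )
            if total > 1.0:
                raise ValueError(f"{kind} class fractions sum to {total} > 1")
        if self.overdispersion_r < 1.0:
            raise ValueError("overdispersion_r must be >= 1")
        if len(self.planted_effects) > self.n_mirna_families:
            raise ValueError("more planted effects than families")

    def family_names(self) -> list[str]:
        planted = list(self.planted_effects)
        rest = [
            f"fam{i:03d}" for i in range(1, self.n_mirna_families - len(planted) + 1)
        ]
        return planted + rest

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# references


def make_references(config: SimulationConfig) -> dict[str, ReferenceSet]:
    """Build every reference set the pipeline matches against.

    Returns sets keyed ``mirna``, ``rrna``, ``trna``, ``mrna``, ``retro``,
    ``pri_mirna`` and ``genome``.  Each mature miRNA (20-24 nt) is named
    for its family and embedded in exactly one pri-miRNA contig; no mature
    sequence occurs in a different family's contig.  The toy genome
    concatenates everything with random spacers.
    """
    config.validate()
    rng = _rng(config, 0)
    families = config.family_names()

    mirna = {}
    for fam in families:
        mirna[fam] = _random_seq(rng, int(rng.integers(20, 25)))

    def transcripts(prefix: str, n: int, lo: int, hi: int) -> dict[str, str]:
        return {
            f"{prefix}{i+1}": _random_seq(rng, int(rng.integers(lo, hi + 1)))
            for i in range(n)
        }

    rrna = transcripts("rrna_", 4, 800, 2000)
    trna = transcripts("trna_", 8, 100, 300)
    mrna = {name: _random_seq(rng, int(rng.integers(500, 2000))) for name in TARGET_MRNAS}
    mrna.update(transcripts("mrna_", 9, 300, 2000))
    retro = transcripts("retro_", 6, 500, 2000)

    # pri-miRNA contigs: random flanks around each mature sequence; reject
    # flanks that accidentally create a cross-family mature occurrence
    pri: dict[str, str] = {}
    others = set(mirna.values())
    for fam, mature in mirna.items():
        while True:
            contig = (
                _random_seq(rng, int(rng.integers(30, 61)))
                + mature
                + _random_seq(rng, int(rng.integers(30, 61)))
            )
            rc = reverse_complement(contig)
            foreign = others - {mature}
            if not any(m in contig or m in rc for m in foreign):
                pri[f"pri_{fam}"] = contig
                break

    genome_parts = []
    for block in (mirna, rrna, trna, mrna, retro, pri):
        for seq in block.values():
            genome_parts.append(seq)
            genome_parts.append(_random_seq(rng, 50))
    genome = {"toy_genome": "".join(genome_parts)}

    return {
        "mirna": ReferenceSet("mirna", mirna),
        "rrna": ReferenceSet("rrna", rrna),
        "trna": ReferenceSet("trna", trna),
        "mrna": ReferenceSet("mrna", mrna),
        "retro": ReferenceSet("retro", retro),
        "pri_mirna": ReferenceSet("pri_mirna", pri),
        "genome": ReferenceSet("genome", genome),
    }


def family_map(references: Mapping[str, ReferenceSet]) -> dict[str, str]:
    """miRNA reference name -> family name (identity here: one mature
    sequence per family, named for the family)."""
    return {name: name for name, _ in references["mirna"]}


# ---------------------------------------------------------------------------
# expression structure


def family_weights(config: SimulationConfig) -> dict[str, float]:
    """Baseline relative family abundances (sum to 1).

    Each planted family holds a fixed 10% share of the baseline (the
    differentially expressed families are among the abundant ones in real
    profiles, and a stable share keeps their counts informative);
    the remaining share is spread log-normally over the other families,
    giving the heavy tail observed in real miRNA abundance profiles.
    """
    rng = _rng(config, 99)
    families = config.family_names()
    planted = list(config.planted_effects)
    rest = [f for f in families if f not in planted]
    planted_share = 0.10
    weights = {fam: planted_share for fam in planted}
    remainder = 1.0 - planted_share * len(planted)
    draws = rng.lognormal(0.0, config.lognormal_sigma, len(rest))
    draws = draws / draws.sum() * remainder
    weights.update({fam: float(w) for fam, w in zip(rest, draws)})
    return weights


def expected_family_means(
    config: SimulationConfig, sample_kind: str
) -> dict[str, float]:
    """True per-family expected counts for one sample kind."""
    weights = family_weights(config)
    n_reads = (
        config.reads_ancient if sample_kind == "ancient" else config.reads_per_control
    )
    srna_frac = getattr(config, f"srna_fraction_{_frac_key(sample_kind)}")
    base_total = config.mirna_fraction * srna_frac * n_reads
    means = {}
    for fam, w in weights.items():
        fold = (
            config.planted_effects.get(fam, 1.0) if sample_kind == "ancient" else 1.0
        )
        means[fam] = w * base_total * fold
    return means


def _frac_key(sample_kind: str) -> str:
    if sample_kind == "ancient":
        return "ancient"
    if sample_kind == "modern":
        return "modern"
    raise ValueError(f"unknown sample_kind {sample_kind!r}")


def _nb_sample(rng: np.random.Generator, mean: float, r: float) -> int:
    """Negative-binomial draw with variance r·mean (Poisson when r=1)."""
    if mean <= 0:
        return 0
    if r <= 1.0 + 1e-9:
        return int(rng.poisson(mean))
    n = mean / (r - 1.0)
    p = 1.0 / r
    return int(rng.negative_binomial(n, p))


# ---------------------------------------------------------------------------
# libraries


def simulate_library(
    config: SimulationConfig,
    references: Mapping[str, ReferenceSet],
    sample_kind: str,
    sample_index: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """One library: list of (read_id, read_sequence) plus its truth table.

    Reads are drawn per molecular class according to the configured
    fractions; miRNA reads are exact mature sequences drawn family-wise
    with negative-binomial counts; other classes contribute random
    18-25 nt fragments (sRNA-sized breakdown products) or 26-44 nt
    fragments (the non-sRNA remainder, removed later by the size filter).
    Ancient reads receive independent C->T substitutions at
    ``deamination_rate`` on the sequenced strand.  The adapter is appended
    and the read truncated to ``read_length``.
    """
    config.validate()
    kind_code = {"ancient": 1, "modern": 2}.get(sample_kind)
    if kind_code is None:
        raise ValueError(f"unknown sample_kind {sample_kind!r}")
    if sample_kind == "modern" and not 0 <= sample_index < config.n_controls:
        raise ValueError(f"sample_index {sample_index} out of range")
    if sample_kind == "ancient" and sample_index != 0:
        raise ValueError("the ancient library is singleplex (sample_index 0)")
    rng = _rng(config, kind_code, sample_index)

    n_reads = (
        config.reads_ancient if sample_kind == "ancient" else config.reads_per_control
    )
    srna_frac = getattr(config, f"srna_fraction_{_frac_key(sample_kind)}")
    rrna_frac = getattr(config, f"rrna_fraction_{_frac_key(sample_kind)}")
    retro_frac = getattr(config, f"retro_fraction_{_frac_key(sample_kind)}")
    # modern controls vary in composition; the single ancient library and
    # the overall sRNA-size fraction stay at their configured values
    if sample_kind == "modern" and config.class_fraction_rel_sd > 0:
        rrna_frac = float(
            np.clip(rrna_frac * rng.normal(1.0, config.class_fraction_rel_sd), 0, 0.95)
        )
        retro_frac = float(
            np.clip(retro_frac * rng.normal(1.0, config.class_fraction_rel_sd), 0, 0.2)
        )

    n_srna = int(rng.binomial(n_reads, srna_frac))
    mean_factor = config.mirna_fraction * srna_frac * n_reads
    weights = family_weights(config)
    fam_counts: dict[str, int] = {}
    for fam, w in weights.items():
        fold = (
            config.planted_effects.get(fam, 1.0) if sample_kind == "ancient" else 1.0
        )
        fam_counts[fam] = _nb_sample(rng, w * mean_factor * fold, config.overdispersion_r)
    n_mirna = sum(fam_counts.values())
    n_rrna = int(round(rrna_frac * n_srna))
    n_retro = int(round(retro_frac * n_srna))
    remainder = max(n_srna - n_mirna - n_rrna - n_retro, 0)
    n_trna = remainder // 3
    n_mrna = remainder - n_trna
    n_long = n_reads - n_srna

    sample_id = (
        "ancient" if sample_kind == "ancient" else f"control{sample_index:02d}"
    )
    mirna_seqs = dict(references["mirna"])
    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    counter = 0

    def emit(insert: str, true_class: str, fam: str, ref: str, strand: str, pos: int,
             size_class: str) -> None:
        nonlocal counter
        damage_positions: list[int] = []
        read = insert
        if sample_kind == "ancient" and config.deamination_rate > 0:
            chars = list(read)
            for i, b in enumerate(chars):
                if b == "C" and rng.random() < config.deamination_rate:
                    chars[i] = "T"
                    damage_positions.append(i)
            read = "".join(chars)
        read = (read + config.adapter_seq)[: config.read_length]
        read_id = f"{sample_id}_r{counter:07d}"
        counter += 1
        records.append((read_id, read))
        truth_rows.append(
            {
                "read_id": read_id,
                "sample_id": sample_id,
                "sample_kind": sample_kind,
                "size_class": size_class,
                "true_class": true_class,
                "family": fam,
                "source_ref": ref,
                "strand": strand,
                "position": pos,
                "insert_len": len(insert),
                "damage_positions": ";".join(map(str, damage_positions)),
            }
        )

    def fragment(refset: ReferenceSet, lo: int, hi: int,
                 ref_weights: dict[str, float] | None = None) -> tuple[str, str, str, int]:
        names = list(refset.sequences)
        if ref_weights:
            probs = np.array([ref_weights.get(n, 1.0) for n in names], dtype=float)
            probs /= probs.sum()
            name = names[int(rng.choice(len(names), p=probs))]
        else:
            name = names[int(rng.integers(len(names)))]
        seq = refset.sequences[name]
        length = int(rng.integers(lo, hi + 1))
        length = min(length, len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))
        window = seq[start : start + length]
        if rng.random() < 0.5:
            return reverse_complement(window), name, "-", start
        return window, name, "+", start

    # miRNA reads: the mature sequence itself, forward strand
    for fam, count in fam_counts.items():
        for _ in range(count):
            emit(mirna_seqs[fam], "mirna", fam, fam, "+", 0, "srna")

    mrna_weights = None
    if sample_kind == "ancient" and config.target_ratio_ancient != 1.0:
        pcf_w = config.target_ratio_ancient / 2.0
        mrna_weights = {"PCF5": pcf_w, "PCF6": pcf_w, "GAMYB": 1.0}

    for cls, count, weights_ in (
        ("rrna", n_rrna, None),
        ("retro", n_retro, None),
        ("trna", n_trna, None),
        ("mrna", n_mrna, mrna_weights),
    ):
        refset = references[cls]
        for _ in range(count):
            insert, ref, strand, pos = fragment(refset, 18, 25, weights_)
            emit(insert, cls, "", ref, strand, pos, "srna")

    # non-sRNA remainder: longer breakdown fragments, mostly ribosomal
    long_sources = ("rrna", "mrna")
    for _ in range(n_long):
        cls = long_sources[int(rng.random() < 0.3)]
        insert, ref, strand, pos = fragment(references[cls], 26, 44)
        emit(insert, cls, "", ref, strand, pos, "long")

    truth = pd.DataFrame(truth_rows)
    return records, truth


def write_fastq(records: Sequence[tuple[str, str]], path: str | Path) -> Path:
    """Write (id, sequence) records as Phred+33 FASTQ, constant quality."""
    path = Path(path)
    with open(path, "w") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


# ---------------------------------------------------------------------------
# PIA inputs


def make_taxonomy() -> Taxonomy:
    """A small rooted taxonomy with barley (hordeum) as the focal taxon."""
    parent = {
        "root": None,
        "cellular": "root",
        "bacteria": "cellular",
        "e_coli": "bacteria",
        "bacillus": "bacteria",
        "eukaryota": "cellular",
        "fungi": "eukaryota",
        "aspergillus": "fungi",
        "metazoa": "eukaryota",
        "homo": "metazoa",
        "viridiplantae": "eukaryota",
        "poaceae": "viridiplantae",
        "hordeum": "poaceae",
        "triticum": "poaceae",
        "oryza": "poaceae",
    }
    return Taxonomy(parent=parent, target="hordeum")


def make_pia_dataset(
    config: SimulationConfig,
    references: Mapping[str, ReferenceSet],
    n_sequences: int = 500,
    endogenous_fraction: float = 0.9,
    tie_rate: float = 0.1,
) -> tuple[dict[str, str], list[HitList], dict[str, float], Taxonomy, pd.DataFrame]:
    """Unique sequences + hit lists + redundancy table with known truth.

    Endogenous sequences are genome fragments with plant-lineage hit
    lists; exogenous ones are random sequences absent from the genome
    with bacterial/fungal/human hits.  ``tie_rate`` of hit lists get a
    tied top score (discarded by the tie filter).  Returns (sequences,
    hitlists, redundancy, taxonomy, truth) keyed by query id.
    """
    rng = _rng(config, 7)
    genome = references["genome"].sequences["toy_genome"]
    taxonomy = make_taxonomy()
    sequences: dict[str, str] = {}
    hitlists: list[HitList] = []
    redundancy: dict[str, float] = {}
    rows = []
    plant_pairs = [("hordeum", "triticum"), ("hordeum", "oryza"), ("hordeum", "poaceae")]
    exo_pairs = [("e_coli", "bacillus"), ("aspergillus", "fungi"), ("homo", "metazoa")]
    for i in range(n_sequences):
        qid = f"q{i:05d}"
        endo = rng.random() < endogenous_fraction
        if endo:
            length = int(rng.integers(18, 26))
            start = int(rng.integers(0, len(genome) - length + 1))
            seq = genome[start : start + length]
            taxa = plant_pairs[int(rng.integers(len(plant_pairs)))]
        else:
            while True:
                seq = _random_seq(rng, int(rng.integers(18, 26)))
                if seq not in genome and reverse_complement(seq) not in genome:
                    break
            taxa = exo_pairs[int(rng.integers(len(exo_pairs)))]
        top = float(rng.integers(80, 120))
        second = top if rng.random() < tie_rate else top - float(rng.integers(1, 20))
        sequences[qid] = seq
        hitlists.append(HitList(qid, [(taxa[0], top), (taxa[1], second)]))
        redundancy[qid] = float(rng.integers(1, 20))
        rows.append({"query_id": qid, "endogenous": endo})
    truth = pd.DataFrame(rows)
    return sequences, hitlists, redundancy, taxonomy, truth


# ---------------------------------------------------------------------------
# whole-experiment convenience


def write_experiment(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate references plus all libraries and write them under outdir.

    Layout: ``refs/<class>.fasta``, ``reads/<sample>.fastq``,
    ``truth/<sample>.tsv``, ``truth/family_means.tsv``, ``config.yaml``.
    Returns a manifest of written paths.
    """
    outdir = Path(outdir)
    (outdir / "refs").mkdir(parents=True, exist_ok=True)
    (outdir / "reads").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    references = make_references(config)
    manifest: dict = {"refs": {}, "reads": {}, "truth": {}}
    for cls, refset in references.items():
        manifest["refs"][cls] = str(refset.write_fasta(outdir / "refs" / f"{cls}.fasta"))
    samples = [("ancient", 0)] + [("modern", i) for i in range(config.n_controls)]
    for kind, idx in samples:
        records, truth = simulate_library(config, references, kind, idx)
        sid = truth["sample_id"].iloc[0]
        manifest["reads"][sid] = str(
            write_fastq(records, outdir / "reads" / f"{sid}.fastq")
        )
        tpath = outdir / "truth" / f"{sid}.tsv"
        truth.to_csv(tpath, sep="\t", index=False)
        manifest["truth"][sid] = str(tpath)
    means = []
    for kind in ("ancient", "modern"):
        for fam, mu in expected_family_means(config, kind).items():
            means.append({"sample_kind": kind, "family": fam, "true_mean": mu})
    pd.DataFrame(means).to_csv(outdir / "truth" / "family_means.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")
    manifest["config"] = str(outdir / "config.yaml")
    return manifest
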