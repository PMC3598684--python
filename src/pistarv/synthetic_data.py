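"""Synthetic two-tissue, two-treatment paired-end RNA-Seq experiment with
known ground truth.

The generator emulates the study design this pipeline targets: a
phosphate-replete control versus phosphate-starved (-P) treatment, two
tissues (root, shoot), three replicates each — twelve libraries of 100-bp
paired-end reads with ~260-bp inserts — over a transcript set that also
yields a redundant contig pool (contained fragments, isoform variants),
cross-species ortholog hit tables with decoys, and 1-kb promoters with
planted P1BS (GNATATNC) motifs.

Every planted artifact is recorded in :class:`GroundTruth` so downstream
stages (de-redundancy, mapping, quantification, differential-expression
calling, orthology, motif scanning) can be scored exactly.

Determinism: one global seed drives an independent named stream per
purpose, so e.g. the promoter set can be regenerated without re-simulating
the libraries.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field, fields

import numpy as np

from .io_formats import HitRecord, SequenceRecord, reverse_complement

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "GroundTruth",
    "simulate_transcriptome",
    "assign_de_labels",
    "simulate_counts",
    "simulate_library",
    "derive_contig_set",
    "simulate_cross_species",
    "simulate_promoters",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CONTROL = "control"
STARVED = "starved"
TREATMENTS = (CONTROL, STARVED)


class ConfigError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Lengths are drawn from a log-normal (natural-log mean/sd) floored at
    twice the read length; defaults give a median transcript of ~700 bp,
    matching typical de novo assemblies of plant transcriptomes.
    """

    seed: int = 0
    n_transcripts: int = 2000
    length_log_mean: float = 6.55
    length_log_sd: float = 0.7
    read_length: int = 100
    insert_mean: int = 260
    insert_sd: float = 30.0
    error_rate: float = 0.005
    n_replicates: int = 3
    tissues: tuple[str, ...] = ("root", "shoot")
    de_fraction: float = 0.10
    de_fold_range: tuple[float, float] = (2.0, 8.0)
    library_depth: int = 50_000
    # contig derivation
    containment_fraction: float = 0.30
    containment_identity: float = 0.95
    containment_span: tuple[float, float] = (0.30, 0.90)
    isoform_fraction: float = 0.10
    # cross-species comparison
    ortholog_fraction: float = 0.50
    ortholog_identity_range: tuple[float, float] = (65.0, 95.0)
    ortholog_coverage_range: tuple[float, float] = (65.0, 100.0)
    ortholog_evalue_max: float = 1e-10
    decoy_fraction: float = 0.50
    # promoters
    n_promoters: int = 200
    promoter_length: int = 1000
    motif_fraction: float = 0.50

    def validate(self) -> list[str]:
        """Return all violations (empty list when valid)."""
        errs: list[str] = []
        if self.read_length > self.insert_mean:
            errs.append("read_length must be <= insert_mean")
        for name in ("n_transcripts", "read_length", "insert_mean",
                     "n_replicates", "library_depth", "n_promoters",
                     "promoter_length"):
            if getattr(self, name) < 1:
                errs.append(f"{name} must be >= 1")
        for name in ("error_rate", "de_fraction", "containment_fraction",
                     "isoform_fraction", "ortholog_fraction",
                     "decoy_fraction", "motif_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                errs.append(f"{name} must be in [0, 1]")
        if not 0.0 < self.containment_identity <= 1.0:
            errs.append("containment_identity must be in (0, 1]")
        if self.de_fold_range[0] <= 1.0:
            errs.append("de_fold_range minimum must be > 1")
        if len(self.tissues) < 1:
            errs.append("at least one tissue required")
        return errs

    def check(self) -> "SimulationConfig":
        errs = self.validate()
        if errs:
            raise ConfigError("; ".join(errs))
        return self


@dataclass
class GroundTruth:
    """The simulator's hidden truth, closed over every planted artifact."""

    transcript_ids: list[str] = field(default_factory=list)
    lengths: dict[str, int] = field(default_factory=dict)
    abundance: dict[str, float] = field(default_factory=dict)
    #: tissue -> transcript -> (label in {up, down}, true fold applied under -P)
    de_labels: dict[str, dict[str, tuple[str, float]]] = field(default_factory=dict)
    #: (tissue, treatment, replicate) -> transcript -> expected pair count
    expected_counts: dict[tuple[str, str, int], dict[str, float]] = field(default_factory=dict)
    #: (tissue, treatment, replicate) -> transcript -> realized pair count
    realized_counts: dict[tuple[str, str, int], dict[str, int]] = field(default_factory=dict)
    #: (contained contig id, container contig id, exact planted identity)
    containment_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    #: locus id -> member contig ids (full transcript + isoform variants)
    isoform_loci: dict[str, list[str]] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    #: (a, b) -> (planted identity %, planted query coverage %)
    ortholog_quality: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    #: promoter id -> [(0-based start, strand)]
    motif_positions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def true_fold(self, tissue: str, transcript_id: str) -> float:
        label = self.de_labels.get(tissue, {}).get(transcript_id)
        return label[1] if label else 1.0


def _rng(seed: int, purpose: str) -> np.random.Generator:
    """Named independent stream derived from the global seed."""
    return np.random.default_rng([seed, zlib.crc32(purpose.encode())])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def simulate_transcriptome(config: SimulationConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Draw the transcript set and per-transcript baseline abundances.

    Lengths are log-normal floored at ``2 * read_length``; bases are i.i.d.
    uniform. Byte-identical output for identical configs.
    """
    config.check()
    rng = _rng(config.seed, "transcriptome")
    n = config.n_transcripts
    lengths = rng.lognormal(config.length_log_mean, config.length_log_sd, size=n)
    lengths = np.maximum(lengths.astype(int), 2 * config.read_length)
    truth = GroundTruth()
    records = []
    for i in range(n):
        tid = f"t{i:05d}"
        seq = _random_seq(rng, int(lengths[i]))
        records.append(SequenceRecord(id=tid, sequence=seq))
        truth.transcript_ids.append(tid)
        truth.lengths[tid] = int(lengths[i])
    abund = rng.lognormal(0.0, 1.0, size=n)
    truth.abundance = {tid: float(a) for tid, a in zip(truth.transcript_ids, abund)}
    assign_de_labels(truth, config)
    return records, truth


def assign_de_labels(truth: GroundTruth, config: SimulationConfig) -> None:
    """Designate ``de_fraction`` of transcripts per tissue as up/down under
    -P, with true folds drawn uniformly from ``de_fold_range``."""
    rng = _rng(config.seed, "de-labels")
    n = len(truth.transcript_ids)
    n_de = int(round(config.de_fraction * n))
    lo, hi = config.de_fold_range
    truth.de_labels = {}
    for tissue in config.tissues:
        chosen = rng.choice(n, size=n_de, replace=False)
        folds = rng.uniform(lo, hi, size=n_de)
        up = rng.random(n_de) < 0.5
        labels: dict[str, tuple[str, float]] = {}
        for idx, fold, is_up in zip(chosen, folds, up):
            tid = truth.transcript_ids[int(idx)]
            labels[tid] = ("up", float(fold)) if is_up else ("down", 1.0 / float(fold))
        truth.de_labels[tissue] = labels


def _expected_counts(truth: GroundTruth, tissue: str, treatment: str,
                     config: SimulationConfig) -> np.ndarray:
    """Expected pair counts: abundance x length, times true fold under -P,
    normalized to the library depth."""
    ids = truth.transcript_ids
    w = np.array([truth.abundance[t] * truth.lengths[t] for t in ids])
    if treatment == STARVED:
        fold = np.array([truth.true_fold(tissue, t) for t in ids])
        w = w * fold
    return w / w.sum() * config.library_depth


def simulate_counts(truth: GroundTruth, tissue: str, treatment: str,
                    replicate: int, config: SimulationConfig) -> dict[str, int]:
    """Realized per-transcript pair counts for one library (Poisson around
    the expectation). Records both expectation and realization in truth."""
    if treatment not in TREATMENTS:
        raise ConfigError(f"unknown treatment {treatment!r}")
    if tissue not in config.tissues:
        raise ConfigError(f"unknown tissue {tissue!r}")
    expected = _expected_counts(truth, tissue, treatment, config)
    rng = _rng(config.seed, f"counts/{tissue}/{treatment}/{replicate}")
    realized = rng.poisson(expected)
    key = (tissue, treatment, replicate)
    truth.expected_counts[key] = {
        t: float(e) for t, e in zip(truth.transcript_ids, expected)
    }
    truth.realized_counts[key] = {
        t: int(c) for t, c in zip(truth.transcript_ids, realized)
    }
    return truth.realized_counts[key]


def simulate_library(
    transcripts: list[SequenceRecord],
    truth: GroundTruth,
    tissue: str,
    treatment: str,
    replicate: int,
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], dict[str, int]]:
    """Emit one paired-end library (R1, R2) in FR orientation.

    Fragments are drawn with a normal insert-length distribution clipped to
    [read_length, transcript length]; mate 1 is the 5' read of the fragment,
    mate 2 the reverse complement of its 3' end. Substitution errors are
    applied at ``error_rate`` per base. Read ids encode the source
    transcript (``{library}:{serial}:{source}``) so mapping can be scored
    against truth.
    """
    counts = simulate_counts(truth, tissue, treatment, replicate, config)
    lib = f"{tissue}_{treatment}_rep{replicate}"
    rng = _rng(config.seed, f"reads/{lib}")
    rl = config.read_length
    qual = "I" * rl
    by_id = {rec.id: rec.sequence for rec in transcripts}
    r1: list[SequenceRecord] = []
    r2: list[SequenceRecord] = []
    serial = 0
    for tid in truth.transcript_ids:
        c = counts[tid]
        if c == 0:
            continue
        seq = by_id[tid]
        L = len(seq)
        inserts = np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_sd, size=c)),
            rl, L,
        ).astype(int)
        starts = rng.integers(0, L - inserts + 1)
        n_errs = rng.binomial(rl, config.error_rate, size=2 * c)
        for j in range(c):
            s, ins = int(starts[j]), int(inserts[j])
            m1 = seq[s:s + rl]
            m2 = reverse_complement(seq[s + ins - rl:s + ins])
            if n_errs[2 * j]:
                m1 = _mutate(m1, int(n_errs[2 * j]), rng)
            if n_errs[2 * j + 1]:
                m2 = _mutate(m2, int(n_errs[2 * j + 1]), rng)
            pair_id = f"{lib}:{serial}:{tid}"
            serial += 1
            r1.append(SequenceRecord(id=pair_id, sequence=m1, quality=qual))
            r2.append(SequenceRecord(id=pair_id, sequence=m2, quality=qual))
    return r1, r2, counts


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in pos:
        choices = BASES[BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _mutate_exact(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Exactly n_subs substitutions at distinct positions."""
    return _mutate(seq, n_subs, rng) if n_subs else seq


def derive_contig_set(
    transcripts: list[SequenceRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[SequenceRecord]:
    """Emulate a redundant assembler output over the transcript set.

    Every transcript is emitted in full (locus label in the description).
    A ``containment_fraction`` of transcripts additionally yields a
    contained fragment (30-90% span) carrying exactly
    ``round((1 - containment_identity) * span)`` substitutions, so the
    planted identity is exact. An ``isoform_fraction`` of loci yields 1-3
    isoform-length variants sharing the locus id; each variant couples a
    shared core (<=80% of the transcript) to a unique flank so that no
    variant is contained in another at >=90% coverage.
    """
    config.check()
    rng = _rng(config.seed, "contigs")
    contigs: list[SequenceRecord] = []
    truth.containment_pairs = []
    truth.isoform_loci = {}
    plain = config.containment_fraction == 0 and config.isoform_fraction == 0
    for rec in transcripts:
        if plain:
            contigs.append(rec)
            continue
        tid, seq = rec.id, rec.sequence
        L = len(seq)
        contigs.append(SequenceRecord(id=tid, sequence=seq, description=f"locus={tid}"))
        roll = rng.random()
        if roll < config.containment_fraction:
            lo, hi = config.containment_span
            span = max(int(rng.uniform(lo, hi) * L), 30)
            start = int(rng.integers(0, L - span + 1))
            n_subs = int(round((1.0 - config.containment_identity) * span))
            frag = _mutate_exact(seq[start:start + span], n_subs, rng)
            fid = f"{tid}.frag"
            contigs.append(SequenceRecord(id=fid, sequence=frag, description=f"locus={tid}"))
            truth.containment_pairs.append((fid, tid, 1.0 - n_subs / span))
        elif roll < config.containment_fraction + config.isoform_fraction:
            n_iso = int(rng.integers(1, 4))
            members = [tid]
            for j in range(n_iso):
                # unique flank at 80% of the core: even with the ~60%
                # residual identity optimal alignment finds between random
                # sequences, the variant stays well under the 90%
                # containment gate
                core_frac = rng.uniform(0.42, 0.52)
                core_len = int(core_frac * L)
                core_start = int(rng.integers(0, L - core_len + 1))
                ext = _random_seq(rng, max(int(0.80 * core_len), 40))
                var_seq = ext + seq[core_start:core_start + core_len]
                vid = f"{tid}.iso{j + 1}"
                contigs.append(
                    SequenceRecord(id=vid, sequence=var_seq, description=f"locus={tid}")
                )
                members.append(vid)
            truth.isoform_loci[tid] = members
    return contigs


def simulate_cross_species(
    transcripts: list[SequenceRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[HitRecord], list[HitRecord]]:
    """Synthetic second species (protein set) plus reciprocal hit tables.

    For each designated ortholog pair the two directional hits are mutual
    tops (identity/coverage from the configured ranges, e-values at or
    below the configured maximum). Decoy hits at strictly lower bitscore
    and higher e-value are attached to a ``decoy_fraction`` of queries;
    decoys only ever point at partnered subjects, so no spurious
    reciprocal-top pair can arise.
    """
    config.check()
    rng = _rng(config.seed, "cross-species")
    ids = truth.transcript_ids
    n_orth = int(round(config.ortholog_fraction * len(ids)))
    chosen = sorted(rng.choice(len(ids), size=n_orth, replace=False).tolist())
    truth.ortholog_pairs = []
    truth.ortholog_quality = {}
    proteins: list[SequenceRecord] = []
    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    aa = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
    id_lo, id_hi = config.ortholog_identity_range
    cov_lo, cov_hi = config.ortholog_coverage_range
    partnered_b: list[str] = []
    base_bitscore: dict[str, float] = {}
    for rank, idx in enumerate(chosen):
        a = ids[idx]
        b = f"os{rank:05d}"
        plen = max(truth.lengths[a] // 3, 60)
        proteins.append(
            SequenceRecord(id=b, sequence=rng.choice(aa, size=plen).tobytes().decode())
        )
        ident = float(rng.uniform(id_lo, id_hi))
        cov = float(rng.uniform(cov_lo, min(cov_hi, 100.0)))
        evalue = float(10.0 ** rng.uniform(-50, np.log10(config.ortholog_evalue_max)))
        bitscore = float(rng.uniform(300, 1000))
        qlen_a = truth.lengths[a]
        aln_a = max(int(round(cov / 100.0 * qlen_a)), 1)
        hits_ab.append(HitRecord(a, b, round(ident, 2), aln_a,
                                 int((1 - ident / 100) * aln_a), 0,
                                 1, aln_a, 1, min(aln_a, plen),
                                 evalue, round(bitscore, 1)))
        aln_b = max(int(round(cov / 100.0 * plen)), 1)
        hits_ba.append(HitRecord(b, a, round(ident, 2), aln_b,
                                 int((1 - ident / 100) * aln_b), 0,
                                 1, aln_b, 1, min(aln_b, qlen_a),
                                 evalue, round(bitscore, 1)))
        truth.ortholog_pairs.append((a, b))
        truth.ortholog_quality[(a, b)] = (round(ident, 2),
                                          round(aln_a / qlen_a * 100.0, 4))
        partnered_b.append(b)
        base_bitscore[a] = bitscore
        base_bitscore[b] = bitscore
    # decoys: weaker extra hits for partnered queries, and sole (one-sided)
    # hits for a sample of unpartnered wheat queries
    partnered_a = [ids[i] for i in chosen]
    unpartnered = [t for t in ids if t not in set(partnered_a)]
    for a in partnered_a:
        if rng.random() < config.decoy_fraction and partnered_b:
            for b in rng.choice(partnered_b, size=int(rng.integers(1, 3))):
                hits_ab.append(_decoy(a, str(b), base_bitscore[a], rng))
    for b in partnered_b:
        if rng.random() < config.decoy_fraction and partnered_a:
            for a2 in rng.choice(partnered_a, size=int(rng.integers(1, 3))):
                hits_ba.append(_decoy(b, str(a2), base_bitscore[b], rng))
    for a in unpartnered:
        if rng.random() < config.decoy_fraction / 2 and partnered_b:
            hits_ab.append(_decoy(a, str(rng.choice(partnered_b)), 300.0, rng))
    return proteins, hits_ab, hits_ba


def _decoy(query: str, subject: str, top_bitscore: float,
           rng: np.random.Generator) -> HitRecord:
    bs = top_bitscore - float(rng.uniform(20, 150))
    return HitRecord(query, subject, round(float(rng.uniform(30, 55)), 2),
                     200, 100, 2, 1, 200, 1, 200,
                     float(10.0 ** rng.uniform(-8, -2)), round(max(bs, 25.0), 1))


P1BS_RE = re.compile(r"(?=(G[ACGT]ATAT[ACGT]C))")


def simulate_promoters(
    n: int, config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[list[SequenceRecord], dict[str, list[tuple[int, str]]]]:
    """Random 1-kb promoters, a subset carrying 1-3 planted P1BS octamers.

    The background is rejection-sampled free of accidental GNATATNC
    matches, and each emitted sequence is re-scanned so the recorded
    positions are exhaustive. The pattern is its own reverse complement, so
    a '-' strand planting writes the reverse complement of a pattern
    instance — itself a pattern instance; the notional strand is recorded.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    config.check()
    rng = _rng(config.seed, "promoters")
    plen = config.promoter_length
    records: list[SequenceRecord] = []
    positions: dict[str, list[tuple[int, str]]] = {}
    for i in range(n):
        pid = f"prom{i:04d}"
        planted: list[tuple[int, str]] = []
        while True:
            seq = _clean_background(rng, plen)
            planted = []
            if rng.random() < config.motif_fraction:
                k = int(rng.integers(1, 4))
                starts = sorted(rng.choice(plen - 8, size=k, replace=False).tolist())
                if any(b - a < 8 for a, b in zip(starts, starts[1:])):
                    continue  # overlapping plants: redraw
                chars = list(seq)
                for s in starts:
                    octamer = ("G" + _random_seq(rng, 1) + "ATAT"
                               + _random_seq(rng, 1) + "C")
                    strand = "+" if rng.random() < 0.5 else "-"
                    if strand == "-":
                        octamer = reverse_complement(octamer)
                    chars[s:s + 8] = octamer
                    planted.append((s, strand))
                seq = "".join(chars)
            found = sorted(m.start() for m in P1BS_RE.finditer(seq))
            if found == sorted(p for p, _ in planted):
                break
        records.append(SequenceRecord(id=pid, sequence=seq))
        positions[pid] = planted
    if truth is not None:
        truth.motif_positions = positions
    return records, positions


def _clean_background(rng: np.random.Generator, length: int) -> str:
    """Random sequence with any accidental P1BS octamer resampled away."""
    seq = _random_seq(rng, length)
    for _ in range(50):
        hits = [m.start() for m in P1BS_RE.finditer(seq)]
        if not hits:
            return seq
        chars = list(seq)
        for h in hits:
            chars[h:h + 8] = _random_seq(rng, 8)
        seq = "".join(chars)
    raise RuntimeError("failed to generate motif-free background")
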