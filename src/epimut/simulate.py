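"""Synthetic data: array-like beta matrices and clonal bisulfite amplicon reads.

Two generators back the test substrate for the whole pipeline:

* :func:`simulate_beta_matrix` emulates a 27k-style methylation array export:
  per-probe baseline beta values, Gaussian noise clipped to [0, 1], a proband
  with planted epimutations of known sign and size, optional technical
  replicates of the proband, and probe annotations (chromosome, imprinted
  flag).  A truth table records the planted probes.

* :func:`simulate_amplicon_reads` emulates clonally amplified bisulfite
  amplicon reads from two parental alleles: per-CpG methylation drawn per
  allele, bisulfite conversion (unmethylated C -> T) with a configurable
  failure rate at non-CpG cytosines, per-base substitution error, a fraction
  of reads emitted reverse-complemented, and the sample's MID prepended.  A
  truth table records each read's allele and pre-error CpG states.

Both generators are fully reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconSpec, make_amplicon_spec, revcomp
from .array_screen import BetaMatrix

__all__ = [
    "ArraySimConfig",
    "SimulatedArray",
    "plant_epimutations",
    "simulate_beta_matrix",
    "write_array_outputs",
    "ReadSimConfig",
    "SimulatedReads",
    "random_amplicon_spec",
    "simulate_amplicon_reads",
    "write_reads_fasta",
]

_AUTOSOMES = [str(i) for i in range(1, 23)]


# ---------------------------------------------------------------------------
# Array-like beta matrices


@dataclass(frozen=True)
class ArraySimConfig:
    """Conditions for the synthetic array screen substrate.

    Defaults emulate the screen's study design: 18 controls, a proband with
    87 planted epimutations of |delta beta| = 0.35 among 1,000 probes, and
    Gaussian probe noise of SD 0.01 clipped to [0, 1].  Baselines are drawn
    uniformly per probe; planted deltas point away from the nearer boundary
    so the planted value stays inside [0, 1].
    """

    n_controls: int = 18
    n_probes: int = 1000
    baseline_range: tuple[float, float] = (0.1, 0.9)
    baselines: tuple[float, ...] | None = None  # overrides baseline_range
    noise_sd: float = 0.01
    planted: tuple[tuple[int, float], ...] = ()  # (probe index, signed delta)
    replicate_copies: int = 1
    n_sex_probes: int = 0
    n_imprinted_probes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls")
        for idx, _ in self.planted:
            if not 0 <= idx < self.n_probes:
                raise ValueError(f"planted probe index {idx} out of range")


@dataclass(frozen=True)
class SimulatedArray:
    beta: BetaMatrix
    annotation: pd.DataFrame
    truth: pd.DataFrame
    replicate_map: dict[str, str]
    proband: str
    control_ids: tuple[str, ...]


def plant_epimutations(
    n_probes: int,
    n_planted: int,
    magnitude: float,
    baselines: Sequence[float],
    rng: np.random.Generator,
) -> tuple[tuple[int, float], ...]:
    """Choose planted probes and signed deltas that stay within [0, 1].

    The delta is +magnitude when the baseline leaves headroom above, else
    -magnitude, mirroring that real epimutations are hypo- or hyper-
    methylation depending on the locus' normal state.
    """
    if n_planted > n_probes:
        raise ValueError("cannot plant more epimutations than probes")
    idx = rng.choice(n_probes, size=n_planted, replace=False)
    planted = []
    for i in sorted(int(j) for j in idx):
        delta = magnitude if baselines[i] + magnitude <= 1.0 else -magnitude
        planted.append((i, delta))
    return tuple(planted)


def simulate_beta_matrix(cfg: ArraySimConfig) -> SimulatedArray:
    """Generate a beta matrix with planted proband epimutations plus truth.

    Controls are baseline + noise; the proband is baseline + planted delta +
    noise at planted probes and baseline + noise elsewhere.  Replicate copies
    of the proband share the expected value but draw independent noise.
    All values are clipped to [0, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    n_probes = cfg.n_probes
    if cfg.baselines is not None:
        if len(cfg.baselines) != n_probes:
            raise ValueError("baselines length must equal n_probes")
        baselines = np.asarray(cfg.baselines, dtype=float)
    else:
        lo, hi = cfg.baseline_range
        baselines = rng.uniform(lo, hi, size=n_probes)

    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    control_ids = tuple(f"control_{i + 1:02d}" for i in range(cfg.n_controls))
    proband_cols = (
        ["proband"]
        if cfg.replicate_copies == 1
        else [f"proband_rep{i + 1}" for i in range(cfg.replicate_copies)]
    )

    planted_delta = np.zeros(n_probes)
    for idx, delta in cfg.planted:
        planted_delta[idx] = delta

    columns: dict[str, np.ndarray] = {}
    for s in control_ids:
        columns[s] = np.clip(
            baselines + rng.normal(0.0, cfg.noise_sd, size=n_probes), 0.0, 1.0
        )
    proband_expected = np.clip(baselines + planted_delta, 0.0, 1.0)
    for s in proband_cols:
        columns[s] = np.clip(
            proband_expected + rng.normal(0.0, cfg.noise_sd, size=n_probes), 0.0, 1.0
        )

    beta = BetaMatrix(pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id")))

    chromosomes = [_AUTOSOMES[i % len(_AUTOSOMES)] for i in range(n_probes)]
    imprinted = np.zeros(n_probes, dtype=bool)
    # sex-chromosome and imprinted probes (for exercising the filters) are
    # taken from the unplanted tail so they never collide with the signal
    planted_idx = {i for i, _ in cfg.planted}
    free = [i for i in range(n_probes) if i not in planted_idx]
    for k in range(cfg.n_sex_probes):
        chromosomes[free[k]] = "X" if k % 2 == 0 else "Y"
    for k in range(cfg.n_imprinted_probes):
        imprinted[free[cfg.n_sex_probes + k]] = True
    annotation = pd.DataFrame(
        {
            "chromosome": chromosomes,
            "gene_symbol": [f"GENE{i}" for i in range(n_probes)],
            "imprinted": imprinted,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    truth = pd.DataFrame(
        [
            {"probe_id": probe_ids[i], "delta": d, "baseline": baselines[i]}
            for i, d in cfg.planted
        ],
        columns=["probe_id", "delta", "baseline"],
    )
    replicate_map = (
        {c: "proband" for c in proband_cols} if cfg.replicate_copies > 1 else {}
    )
    return SimulatedArray(
        beta=beta,
        annotation=annotation,
        truth=truth,
        replicate_map=replicate_map,
        proband="proband",
        control_ids=control_ids,
    )


def write_array_outputs(sim: SimulatedArray, outdir: str | Path) -> dict[str, Path]:
    """Write beta, annotation, truth (and replicate map) TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
    }
    sim.beta.to_tsv(paths["beta"])
    ann = sim.annotation.copy()
    ann["imprinted"] = ann["imprinted"].astype(int)
    ann.to_csv(paths["annotation"], sep="\t")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    if sim.replicate_map:
        paths["replicates"] = outdir / "replicates.tsv"
        pd.DataFrame(
            sorted(sim.replicate_map.items()), columns=["sample_id", "group"]
        ).to_csv(paths["replicates"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Bisulfite amplicon reads


@dataclass(frozen=True)
class ReadSimConfig:
    """Conditions for the clonal bisulfite read generator.

    ``per_allele_meth`` maps each allele to its per-CpG methylation
    probabilities (one per CpG of the spec); ``allele_read_counts`` gives the
    number of reads per allele.  Error and conversion-failure rates default
    to 0.5 %, typical of well-behaved amplicon runs; half of the reads are
    emitted reverse-complemented, as in an unstranded library.
    """

    spec: AmpliconSpec
    per_allele_meth: Mapping[str, Sequence[float]]
    allele_read_counts: Mapping[str, int]
    sample: str | None = None  # defaults to the spec's first barcode sample
    conversion_failure_rate: float = 0.005
    error_rate: float = 0.005
    revcomp_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for allele, probs in self.per_allele_meth.items():
            if len(probs) != self.spec.n_cpgs:
                raise ValueError(
                    f"allele {allele!r}: {len(probs)} methylation probabilities "
                    f"for {self.spec.n_cpgs} CpGs"
                )
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"allele {allele!r}: probabilities outside [0, 1]")
        for allele, n in self.allele_read_counts.items():
            if n < 0:
                raise ValueError(f"allele {allele!r}: negative read count")


@dataclass(frozen=True)
class SimulatedReads:
    reads: list[tuple[str, str]]  # (read_id, sequence incl. MID)
    truth: pd.DataFrame


_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def random_amplicon_spec(
    n_cpgs: int = 17,
    n_spacer_tokens: int = 220,
    snp_alleles: tuple[str, str] = ("G", "A"),
    barcodes: Mapping[str, str] | None = None,
    seed: int = 0,
) -> AmpliconSpec:
    """Build a random amplicon reference with an exact CpG count and a SNP.

    The sequence is assembled from tokens that cannot create CpGs at
    junctions ("A", "T", "G", "CA", "CT"), with ``n_cpgs`` "CG" tokens mixed
    in, so the CpG layout is exact by construction and there is a healthy
    supply of non-CpG cytosines for the conversion-rate denominator.  The
    SNP is placed on a bisulfite-invariant base (default G/A) away from any
    CpG.
    """
    rng = np.random.default_rng(seed)
    spacers = ["A", "T", "G", "CA", "CT"]
    tokens = [spacers[i] for i in rng.integers(0, len(spacers), size=n_spacer_tokens)]
    for pos in sorted(rng.choice(n_spacer_tokens, size=n_cpgs, replace=False)):
        tokens.insert(int(pos), "CG")
    reference = "".join(tokens)

    cpg_positions = []
    i = reference.find("CG")
    while i != -1:
        cpg_positions.append(i)
        i = reference.find("CG", i + 1)

    ref_base = snp_alleles[0]
    forbidden = set()
    for p in cpg_positions:
        forbidden.update((p - 1, p, p + 1, p + 2))
    candidates = [
        i
        for i, b in enumerate(reference)
        if b == ref_base and i not in forbidden and 5 < i < len(reference) - 5
    ]
    if not candidates:
        raise ValueError("no suitable SNP position found; increase sequence length")
    snp_pos = int(candidates[rng.integers(0, len(candidates))])

    if barcodes is None:
        barcodes = {"ACGAGTGCGT": "sample_1"}
    return make_amplicon_spec(
        name=f"synthetic_{n_cpgs}cpg",
        reference=reference,
        snp={"position": snp_pos, "alleles": list(snp_alleles)},
        barcodes=barcodes,
    )


def simulate_amplicon_reads(cfg: ReadSimConfig) -> SimulatedReads:
    """Generate clonal bisulfite reads from two alleles plus a truth table.

    Per read: pick the allele (deterministic counts), substitute the allele
    base at the SNP, drop any CpG the allele base destroys, draw each intact
    CpG's methylation from the allele's probability, convert unmethylated and
    non-CpG cytosines to T (non-CpG Cs survive with the conversion-failure
    rate), apply per-base substitution error, optionally reverse-complement,
    and prepend the sample's MID.  The truth table holds the allele,
    orientation and pre-error CpG states (1/0/NA) of every read.
    """
    spec = cfg.spec
    rng = np.random.default_rng(cfg.seed)
    if cfg.sample is None:
        sample = next(iter(spec.barcodes.values()))
    else:
        sample = cfg.sample
    mids = {s: m for m, s in spec.barcodes.items()}
    if sample not in mids:
        raise ValueError(f"sample {sample!r} has no MID in the spec")
    mid = mids[sample]

    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    counter = 0
    for allele in sorted(cfg.allele_read_counts):
        n = cfg.allele_read_counts[allele]
        probs = np.asarray(cfg.per_allele_meth[allele], dtype=float)
        for _ in range(n):
            counter += 1
            read_id = f"read_{counter:06d}"
            seq = list(spec.reference)
            if spec.snp is not None:
                seq[spec.snp.position] = allele

            states: list[float] = []
            methylated_positions = set()
            for i, p in enumerate(spec.cpg_positions):
                intact = seq[p] == "C" and seq[p + 1] == "G"
                if not intact:
                    states.append(float("nan"))
                    continue
                m = rng.random() < probs[i]
                states.append(1.0 if m else 0.0)
                if m:
                    methylated_positions.add(p)

            out = []
            for i, b in enumerate(seq):
                if b == "C" and i not in methylated_positions:
                    # unmethylated CpG C and non-CpG C both convert; non-CpG C
                    # survives with the conversion-failure rate
                    if (
                        i not in spec.cpg_positions
                        and rng.random() < cfg.conversion_failure_rate
                    ):
                        out.append("C")
                    else:
                        out.append("T")
                else:
                    out.append(b)

            if cfg.error_rate > 0.0:
                errs = np.nonzero(rng.random(len(out)) < cfg.error_rate)[0]
                for j in errs:
                    out[j] = _OTHER_BASES[out[j]][rng.integers(0, 3)]

            insert = "".join(out)
            orientation = "+"
            if rng.random() < cfg.revcomp_fraction:
                insert = revcomp(insert)
                orientation = "-"
            reads.append((read_id, mid + insert))

            row = {
                "read_id": read_id,
                "sample": sample,
                "allele": allele,
                "orientation": orientation,
            }
            for i, s in enumerate(states):
                row[f"CpG_{i + 1}"] = "NA" if np.isnan(s) else int(s)
            truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    return SimulatedReads(reads=reads, truth=truth)


def write_reads_fasta(sim: SimulatedReads, outdir: str | Path) -> dict[str, Path]:
    """Write reads.fasta and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"reads": outdir / "reads.fasta", "truth": outdir / "truth.tsv"}
    with open(paths["reads"], "w") as fh:
        for read_id, seq in sim.reads:
            fh.write(f">{read_id}\n{seq}\n")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
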