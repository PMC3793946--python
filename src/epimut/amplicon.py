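"""Deep bisulfite amplicon methylation analysis.

Takes barcoded amplicon reads (FASTA/FASTQ), demultiplexes them by their MID
(multiplex identifier) prefix, aligns each read against the bisulfite
expectation of the amplicon reference, calls the methylation state of every
CpG on the read (C = methylated, T = unmethylated, anything else = missing),
computes a per-read bisulfite conversion rate over non-CpG reference
cytosines, separates parental alleles on a heterozygous SNP inside the
amplicon, and summarises methylation per CpG, per read, per allele and
overall.

Coordinates are 0-based offsets on the analyzed strand of the amplicon
reference; CpG columns are reported 1-based in outputs ("CpG 1..n").
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import Align, SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Snp",
    "AmpliconSpec",
    "AlignmentResult",
    "ReadMethCall",
    "PatternMatrix",
    "QCReport",
    "load_amplicon_spec",
    "read_sequences",
    "demultiplex",
    "bisulfite_align",
    "call_read",
    "filter_reads",
    "assign_alleles",
    "build_pattern_matrix",
    "correct_allelic_imbalance",
    "run_sample",
    "run_pipeline",
    "write_outputs",
]

_VALID_BASES = set("ACGT")


class AmpliconConfigError(ValueError):
    """Raised for invalid amplicon specifications."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Snp:
    """A single-nucleotide variant inside the amplicon, on the analyzed strand."""

    position: int  # 0-based offset in the reference
    alleles: tuple[str, str]
    disrupts_cpg_index: int | None = None  # 0-based index into cpg_positions


@dataclass(frozen=True)
class AmpliconSpec:
    """One amplicon target: reference, CpG layout, optional SNP, barcodes.

    ``reference`` is the genomic-strand sequence of the analyzed strand;
    ``cpg_positions`` holds the 0-based offsets of each CpG's cytosine,
    auto-detected by scanning for ``CG``.
    """

    name: str
    reference: str
    cpg_positions: tuple[int, ...]
    snp: Snp | None = None
    barcodes: dict[str, str] = field(default_factory=dict)  # MID -> sample
    array_cpg_index: int | None = None  # 0-based; the "*" CpG of the figures
    linker: str = ""

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    def non_cpg_c_positions(self) -> tuple[int, ...]:
        """Reference cytosines used for the conversion-rate denominator.

        Excludes CpG cytosines and the SNP position (polymorphic, so not a
        reliable conversion readout).
        """
        cpg = set(self.cpg_positions)
        skip = cpg | ({self.snp.position} if self.snp else set())
        return tuple(
            i for i, b in enumerate(self.reference) if b == "C" and i not in skip
        )

    def disrupting_alleles(self) -> tuple[str, ...]:
        """Alleles that destroy the CpG dinucleotide named by the SNP."""
        if self.snp is None or self.snp.disrupts_cpg_index is None:
            return ()
        p = self.cpg_positions[self.snp.disrupts_cpg_index]
        out = []
        for a in self.snp.alleles:
            seq = list(self.reference)
            seq[self.snp.position] = a
            if not (seq[p] == "C" and seq[p + 1] == "G"):
                out.append(a)
        return tuple(out)

    def allele_observable_bases(self) -> dict[str, set[str]]:
        """Bases each allele can show at the SNP after bisulfite conversion.

        An allele base C can be read as T (converted) or C (conversion
        failure, or methylated if the allele recreates a CpG); any other
        allele base is read as itself.  An observed base consistent with more
        than one allele is ambiguous and such reads stay unassigned.
        """
        if self.snp is None:
            return {}
        out: dict[str, set[str]] = {}
        for a in self.snp.alleles:
            out[a] = {a, "T"} if a == "C" else {a}
        return out


def make_amplicon_spec(
    name: str,
    reference: str,
    snp: Mapping | None = None,
    barcodes: Mapping[str, str] | None = None,
    array_cpg_index: int | None = None,
    linker: str = "",
) -> AmpliconSpec:
    """Build and validate an :class:`AmpliconSpec` from plain values."""
    reference = reference.upper()
    if set(reference) - _VALID_BASES:
        bad = sorted(set(reference) - _VALID_BASES)
        raise AmpliconConfigError(f"reference contains non-ACGT bases: {bad}")
    cpg_positions = tuple(m.start() for m in re.finditer("CG", reference))

    snp_obj: Snp | None = None
    if snp is not None:
        pos = int(snp["position"])
        if not 0 <= pos < len(reference):
            raise AmpliconConfigError(f"SNP position {pos} outside reference")
        alleles = tuple(str(a).upper() for a in snp["alleles"])
        if len(alleles) != 2 or any(a not in _VALID_BASES for a in alleles):
            raise AmpliconConfigError(f"SNP alleles must be two of ACGT: {alleles}")
        disrupts = snp.get("disrupts_cpg_index")
        if disrupts is None:
            # auto-infer: the SNP overlaps a CpG's C or G
            for i, p in enumerate(cpg_positions):
                if pos in (p, p + 1):
                    disrupts = i
                    break
        else:
            disrupts = int(disrupts)
            p = cpg_positions[disrupts]
            if pos not in (p, p + 1):
                raise AmpliconConfigError(
                    f"SNP at {pos} does not overlap CpG index {disrupts} (offset {p})"
                )
        snp_obj = Snp(position=pos, alleles=alleles, disrupts_cpg_index=disrupts)

    barcodes = dict(barcodes or {})
    mids = list(barcodes)
    if any(not m for m in mids):
        raise AmpliconConfigError("empty MID sequence")
    for a in mids:
        for b in mids:
            if a != b and b.startswith(a):
                raise AmpliconConfigError(f"MID {a!r} is a prefix of MID {b!r}")

    spec = AmpliconSpec(
        name=name,
        reference=reference,
        cpg_positions=cpg_positions,
        snp=snp_obj,
        barcodes={m.upper(): s for m, s in barcodes.items()},
        array_cpg_index=array_cpg_index,
        linker=linker.upper(),
    )
    if spec.snp is not None and "C" in spec.snp.alleles and "T" in spec.snp.alleles:
        logger.warning(
            "%s: C/T SNP on the analyzed strand; an observed T is ambiguous "
            "(allele T vs converted allele C) and such reads stay unassigned",
            name,
        )
    return spec


def load_amplicon_spec(path: str | Path) -> AmpliconSpec:
    """Load an amplicon specification from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "reference" not in cfg:
        raise AmpliconConfigError(f"{path}: expected a mapping with a 'reference' key")
    return make_amplicon_spec(
        name=cfg.get("name", Path(path).stem),
        reference=cfg["reference"],
        snp=cfg.get("snp"),
        barcodes=cfg.get("barcodes"),
        array_cpg_index=cfg.get("array_cpg_index"),
        linker=cfg.get("linker", ""),
    )


# ---------------------------------------------------------------------------
# Reads I/O and demultiplexing


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (optionally gzipped) as (read_id, sequence) pairs.

    Qualities are accepted but ignored: amplicon pipelines of this kind filter
    on conversion rate and alignment identity rather than base quality.
    """
    path = Path(path)
    name = path.name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def _mid_mismatches(mid: str, seq: str) -> int:
    if len(seq) < len(mid):
        return len(mid)
    return sum(1 for a, b in zip(mid, seq) if a != b)


def demultiplex(
    reads: Iterable[tuple[str, str]],
    spec: AmpliconSpec,
    max_mismatches: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Assign reads to samples by MID prefix match, either orientation.

    Matching is exact by default (MIDs are edit-distance robust by design);
    ``max_mismatches=1`` enables fuzzy matching, assigning only when a single
    MID is within range.  The matched MID (and any declared linker
    immediately following it) is trimmed; the returned sequence is in the
    orientation in which the MID matched.  Unmatched reads are collected
    under ``"unassigned"``.
    """
    if not spec.barcodes:
        raise AmpliconConfigError("barcode table is empty")
    out: dict[str, list[tuple[str, str]]] = {s: [] for s in spec.barcodes.values()}
    out["unassigned"] = []
    for read_id, seq in reads:
        assigned = False
        for oriented in (seq, revcomp(seq)):
            hits = [
                (mid, sample)
                for mid, sample in spec.barcodes.items()
                if _mid_mismatches(mid, oriented) <= max_mismatches
            ]
            if len(hits) == 1:
                mid, sample = hits[0]
                trimmed = oriented[len(mid):]
                if spec.linker and trimmed.startswith(spec.linker):
                    trimmed = trimmed[len(spec.linker):]
                out[sample].append((read_id, trimmed))
                assigned = True
            if assigned:
                break
        if not assigned:
            out["unassigned"].append((read_id, seq))
    return out


# ---------------------------------------------------------------------------
# Bisulfite-aware alignment


@dataclass(frozen=True)
class AlignmentResult:
    """Semi-global alignment of one read against the amplicon reference."""

    orientation: str  # "+" read as given, "-" reverse complement
    oriented_seq: str  # the read in reference orientation
    ref_to_read: dict[int, int]  # reference offset -> read offset (aligned cols)
    score: float
    identity: float
    ok: bool
    flag: str = ""


def _ct(seq: str) -> str:
    return seq.replace("C", "T")


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps: reads may be trimmed relative to the full amplicon
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def bisulfite_align(
    seq: str,
    spec: AmpliconSpec,
    min_length: int = 40,
    identity_floor: float = 0.70,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Align a read to the bisulfite expectation of the reference.

    Both read and reference are collapsed to three-letter space (C -> T), so a
    reference C outside a CpG matches a read T (converted) or C (conversion
    failure) without penalty, and CpG cytosines match C or T freely.  Both the
    read as given and its reverse complement are tried; the higher-scoring
    orientation wins.  Equal scores are ambiguous and the read is discarded.
    Identity is assessed over aligned columns at non-C reference positions;
    below ``identity_floor`` the read is flagged unalignable.
    """
    if len(seq) < min_length:
        return AlignmentResult("+", seq, {}, -np.inf, 0.0, False, "too_short")
    if aligner is None:
        aligner = _make_aligner()
    ref = spec.reference
    ref_ct = _ct(ref)
    candidates = []
    for orientation, oriented in (("+", seq), ("-", revcomp(seq))):
        aln = aligner.align(ref_ct, _ct(oriented))[0]
        ref_to_read: dict[int, int] = {}
        for (ts, te), (qs, qe) in zip(*aln.aligned):
            for k in range(te - ts):
                ref_to_read[ts + k] = qs + k
        matches = total = 0
        oriented_ct = _ct(oriented)
        for rpos, qpos in ref_to_read.items():
            if ref[rpos] == "C":
                continue
            total += 1
            if ref_ct[rpos] == oriented_ct[qpos]:
                matches += 1
        identity = matches / total if total else 0.0
        candidates.append(
            AlignmentResult(orientation, oriented, ref_to_read, aln.score, identity, True)
        )
    best = max(candidates, key=lambda c: c.score)
    other = min(candidates, key=lambda c: c.score)
    if best.score == other.score and best.ref_to_read != other.ref_to_read:
        logger.debug("ambiguous orientation (equal scores); read discarded")
        return replace(best, ok=False, flag="ambiguous_orientation")
    if best.identity < identity_floor:
        return replace(best, ok=False, flag="low_identity")
    return best


# ---------------------------------------------------------------------------
# Per-read methylation calling


@dataclass
class ReadMethCall:
    """Per-CpG methylation states and QC for one read.

    ``states`` holds one value per CpG of the spec: 1.0 methylated, 0.0
    unmethylated, NaN missing.
    """

    read_id: str
    sample: str
    orientation: str
    states: np.ndarray
    conversion_rate: float | None
    snp_base: str | None
    allele: str | None = None
    pass_qc: bool = True
    flag: str = ""


def _infer_allele(snp_base: str | None, spec: AmpliconSpec) -> str | None:
    """Map an observed SNP base to the unique compatible allele, else None."""
    if spec.snp is None or snp_base is None:
        return None
    observable = spec.allele_observable_bases()
    compatible = [a for a, bases in observable.items() if snp_base in bases]
    return compatible[0] if len(compatible) == 1 else None


def call_read(
    read_id: str,
    sample: str,
    aln: AlignmentResult,
    spec: AmpliconSpec,
) -> ReadMethCall:
    """Call per-CpG methylation states and the conversion rate of one read.

    At each CpG cytosine a read C is methylated, a T unmethylated, and a gap
    or other base missing.  If the spec's SNP destroys a CpG on one allele,
    reads carrying a base only compatible with a disrupting allele get a
    missing state at that CpG (the dinucleotide does not exist on their
    molecule).  The conversion rate is the fraction of covered non-CpG
    reference cytosines read as T; it is undefined (None) when the read
    covers none.
    """
    read = aln.oriented_seq
    states = np.full(spec.n_cpgs, np.nan)
    if not aln.ok:
        return ReadMethCall(
            read_id, sample, aln.orientation, states, None, None,
            pass_qc=False, flag=aln.flag,
        )

    snp_base: str | None = None
    if spec.snp is not None:
        qpos = aln.ref_to_read.get(spec.snp.position)
        if qpos is not None:
            snp_base = read[qpos]

    inferred = _infer_allele(snp_base, spec)
    disrupting = spec.disrupting_alleles()

    for i, p in enumerate(spec.cpg_positions):
        if spec.snp is not None and spec.snp.disrupts_cpg_index == i:
            # the CpG exists only on the non-disrupting allele
            if inferred is None or inferred in disrupting:
                continue  # stays missing
        qpos = aln.ref_to_read.get(p)
        if qpos is None:
            continue
        base = read[qpos]
        if base == "C":
            states[i] = 1.0
        elif base == "T":
            states[i] = 0.0

    covered = converted = 0
    for p in spec.non_cpg_c_positions():
        qpos = aln.ref_to_read.get(p)
        if qpos is None:
            continue
        covered += 1
        if read[qpos] == "T":
            converted += 1
    conversion_rate = converted / covered if covered else None

    return ReadMethCall(
        read_id, sample, aln.orientation, states, conversion_rate, snp_base,
        pass_qc=True,
    )


# ---------------------------------------------------------------------------
# Filtering, allele assignment, summaries


@dataclass(frozen=True)
class QCReport:
    """Read-level QC bookkeeping for one sample."""

    sample: str
    n_raw: int
    n_aligned: int
    n_pass_conversion: int
    n_assigned: dict[str, int] = field(default_factory=dict)
    n_unassigned: int = 0
    min_reads_ok: bool = True
    mean_conversion: float | None = None


def filter_reads(
    calls: Sequence[ReadMethCall],
    sample: str,
    n_raw: int,
    min_conversion: float = 0.98,
    min_reads: int = 150,
) -> tuple[list[ReadMethCall], QCReport]:
    """Apply the per-read conversion filter and assemble a QC report.

    Reads must have a conversion rate strictly above ``min_conversion``
    (a rate of exactly 0.98 fails the default "above 98 %" rule).  Reads
    whose conversion rate is undefined (no non-CpG reference C covered) are
    dropped as unassessable.  Falling below ``min_reads`` only sets a QC
    flag; the analysis still runs.
    """
    aligned = [c for c in calls if c.pass_qc]
    rates = [c.conversion_rate for c in aligned if c.conversion_rate is not None]
    kept = [
        c
        for c in aligned
        if c.conversion_rate is not None and c.conversion_rate > min_conversion
    ]
    report = QCReport(
        sample=sample,
        n_raw=n_raw,
        n_aligned=len(aligned),
        n_pass_conversion=len(kept),
        min_reads_ok=len(kept) >= min_reads,
        mean_conversion=float(np.mean(rates)) if rates else None,
    )
    if not report.min_reads_ok:
        logger.warning(
            "%s: only %d reads pass QC (floor %d)", sample, len(kept), min_reads
        )
    return kept, report


def assign_alleles(
    calls: Sequence[ReadMethCall], spec: AmpliconSpec
) -> list[ReadMethCall]:
    """Label each read with the allele uniquely compatible with its SNP base.

    Reads with a gap, a third base, or a bisulfite-ambiguous base at the SNP
    stay unassigned, so per-allele read counts may sum to less than the
    total.
    """
    if spec.snp is None:
        raise AmpliconConfigError(
            f"{spec.name}: no informative variant declared; allele separation "
            "is not possible — run the unseparated analysis instead"
        )
    out = []
    for c in calls:
        out.append(replace_call(c, allele=_infer_allele(c.snp_base, spec)))
    return out


def replace_call(call: ReadMethCall, **kw) -> ReadMethCall:
    d = dict(
        read_id=call.read_id,
        sample=call.sample,
        orientation=call.orientation,
        states=call.states,
        conversion_rate=call.conversion_rate,
        snp_base=call.snp_base,
        allele=call.allele,
        pass_qc=call.pass_qc,
        flag=call.flag,
    )
    d.update(kw)
    return ReadMethCall(**d)


@dataclass(frozen=True)
class PatternMatrix:
    """Reads x CpGs state matrix with methylation summaries.

    The underlying "lollipop" data: rows are reads (sorted by read id),
    columns are CpGs 1..n; cells are 1 (methylated), 0 (unmethylated) or NaN
    (missing).  ``overall_mean`` is the fraction of methylated cells among
    non-missing cells; ``per_read_average`` of per-read means is exposed as
    an alternative summary when missingness is uneven.
    """

    sample: str
    scope: str  # "all" or an allele label
    states: pd.DataFrame
    per_cpg_mean: pd.Series
    per_read_mean: pd.Series
    overall_mean: float
    n_reads: int

    @property
    def per_read_average(self) -> float:
        return float(self.per_read_mean.mean())


def build_pattern_matrix(
    calls: Sequence[ReadMethCall], sample: str, scope: str = "all"
) -> PatternMatrix:
    """Assemble the reads x CpGs pattern matrix for one sample/allele scope."""
    if scope != "all":
        calls = [c for c in calls if c.allele == scope]
    if not calls:
        raise AmpliconConfigError(f"{sample}: no reads in scope {scope!r}")
    calls = sorted(calls, key=lambda c: c.read_id)
    n_cpgs = len(calls[0].states)
    columns = [f"CpG_{i + 1}" for i in range(n_cpgs)]
    states = pd.DataFrame(
        np.vstack([c.states for c in calls]),
        index=pd.Index([c.read_id for c in calls], name="read_id"),
        columns=columns,
    )
    per_cpg_mean = states.mean(axis=0, skipna=True)
    per_read_mean = states.mean(axis=1, skipna=True)
    cells = states.to_numpy()
    n_obs = np.count_nonzero(~np.isnan(cells))
    overall = float(np.nansum(cells) / n_obs) if n_obs else float("nan")
    return PatternMatrix(
        sample=sample,
        scope=scope,
        states=states,
        per_cpg_mean=per_cpg_mean,
        per_read_mean=per_read_mean,
        overall_mean=overall,
        n_reads=len(calls),
    )


def correct_allelic_imbalance(mean_allele_a: float, mean_allele_b: float) -> float:
    """Overall methylation corrected for allelic read-count imbalance.

    The unweighted average of the two per-allele means, so an allele that
    amplified better does not dominate the pooled figure.  Both means must
    come from at least one read each (pass NaN-free values).
    """
    for v in (mean_allele_a, mean_allele_b):
        if v is None or not np.isfinite(v):
            raise ValueError("allelic-imbalance correction needs both allele means")
    return (mean_allele_a + mean_allele_b) / 2.0


# ---------------------------------------------------------------------------
# Orchestration


@dataclass(frozen=True)
class SampleResult:
    sample: str
    calls: list[ReadMethCall]
    pooled: PatternMatrix | None  # None when no read passes QC
    by_allele: dict[str, PatternMatrix]
    corrected_mean: float | None
    qc: QCReport


def run_sample(
    reads: Sequence[tuple[str, str]],
    sample: str,
    spec: AmpliconSpec,
    min_conversion: float = 0.98,
    min_reads: int = 150,
    by_allele: bool = False,
    min_length: int = 40,
    identity_floor: float = 0.70,
) -> SampleResult:
    """Align, call, filter and summarise all reads of one sample."""
    aligner = _make_aligner()
    calls = []
    for read_id, seq in reads:
        aln = bisulfite_align(
            seq, spec, min_length=min_length, identity_floor=identity_floor,
            aligner=aligner,
        )
        calls.append(call_read(read_id, sample, aln, spec))
    kept, qc = filter_reads(
        calls, sample, n_raw=len(reads),
        min_conversion=min_conversion, min_reads=min_reads,
    )
    by_allele_matrices: dict[str, PatternMatrix] = {}
    corrected: float | None = None
    if by_allele and spec.snp is not None and kept:
        kept = assign_alleles(kept, spec)
        n_assigned = {a: 0 for a in spec.snp.alleles}
        for c in kept:
            if c.allele is not None:
                n_assigned[c.allele] += 1
        qc = replace(
            qc,
            n_assigned=n_assigned,
            n_unassigned=sum(1 for c in kept if c.allele is None),
        )
        for a in spec.snp.alleles:
            if n_assigned[a]:
                by_allele_matrices[a] = build_pattern_matrix(kept, sample, scope=a)
        if len(by_allele_matrices) == 2:
            a, b = (by_allele_matrices[x].overall_mean for x in spec.snp.alleles)
            corrected = correct_allelic_imbalance(a, b)
    pooled = build_pattern_matrix(kept, sample, scope="all") if kept else None
    return SampleResult(
        sample=sample,
        calls=kept,
        pooled=pooled,
        by_allele=by_allele_matrices,
        corrected_mean=corrected,
        qc=qc,
    )


def run_pipeline(
    reads: Sequence[tuple[str, str]],
    spec: AmpliconSpec,
    min_conversion: float = 0.98,
    min_reads: int = 150,
    by_allele: bool = False,
    **kwargs,
) -> dict[str, SampleResult]:
    """Demultiplex and analyse every sample in the barcode table."""
    demux = demultiplex(reads, spec)
    results: dict[str, SampleResult] = {}
    for sample, sample_reads in demux.items():
        if sample == "unassigned" or not sample_reads:
            continue
        results[sample] = run_sample(
            sample_reads, sample, spec,
            min_conversion=min_conversion, min_reads=min_reads,
            by_allele=by_allele, **kwargs,
        )
    return results


# ---------------------------------------------------------------------------
# Output


def write_outputs(
    results: Mapping[str, SampleResult], outdir: str | Path
) -> dict[str, Path]:
    """Write pattern, summary and QC TSVs for a pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pattern": outdir / "pattern.tsv",
        "summary": outdir / "summary.tsv",
        "qc": outdir / "qc.tsv",
    }

    pattern_rows = []
    for res in results.values():
        for c in res.calls:
            row = {
                "read_id": c.read_id,
                "sample": c.sample,
                "allele": c.allele if c.allele is not None else "NA",
                "conversion_rate": round(c.conversion_rate, 6)
                if c.conversion_rate is not None
                else "NA",
            }
            for i, s in enumerate(c.states):
                row[f"CpG_{i + 1}"] = "NA" if np.isnan(s) else int(s)
            pattern_rows.append(row)
    pd.DataFrame(pattern_rows).to_csv(paths["pattern"], sep="\t", index=False)

    summary_rows = []
    for res in results.values():
        matrices = ([res.pooled] if res.pooled is not None else []) + list(
            res.by_allele.values()
        )
        for m in matrices:
            row = {
                "sample": m.sample,
                "scope": m.scope,
                "n_reads": m.n_reads,
                "overall_mean": round(m.overall_mean, 6),
            }
            for col, v in m.per_cpg_mean.items():
                row[col] = "NA" if np.isnan(v) else round(float(v), 6)
            summary_rows.append(row)
        if res.corrected_mean is not None:
            summary_rows.append(
                {
                    "sample": res.sample,
                    "scope": "imbalance_corrected",
                    "n_reads": sum(m.n_reads for m in res.by_allele.values()),
                    "overall_mean": round(res.corrected_mean, 6),
                }
            )
    pd.DataFrame(summary_rows).to_csv(paths["summary"], sep="\t", index=False)

    qc_rows = []
    for res in results.values():
        qc = res.qc
        qc_rows.append(
            {
                "sample": qc.sample,
                "n_raw": qc.n_raw,
                "n_aligned": qc.n_aligned,
                "n_pass_conversion": qc.n_pass_conversion,
                "n_unassigned": qc.n_unassigned,
                **{f"n_allele_{a}": n for a, n in qc.n_assigned.items()},
                "min_reads_ok": qc.min_reads_ok,
                "mean_conversion": round(qc.mean_conversion, 6)
                if qc.mean_conversion is not None
                else "NA",
            }
        )
    pd.DataFrame(qc_rows).to_csv(paths["qc"], sep="\t", index=False)
    return paths


def read_pattern_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the pattern TSV (states as floats with NaN)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in df.columns:
        if col.startswith("CpG_") or col == "conversion_rate":
            df[col] = df[col].astype(float)
    return df
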