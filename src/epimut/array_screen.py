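"""Pseudoproband (leave-one-out permutation) screen for aberrant CpG methylation.

The screen operates on an array-style matrix of beta values (fraction of
methylated signal per CpG probe, 0.0 = unmethylated, 1.0 = fully methylated).
Each sample is assigned in turn as a *pseudoproband* and its beta value at
every retained probe is compared against the mean beta of all other samples.
Probes where the absolute difference meets the threshold (default 0.3) are
called aberrant, with a direction (hypomethylated when the pseudoproband is
below the reference mean, hypermethylated when above).

The per-sample aberrant-CpG counts feed three summary statistics:

* the distance of the proband's count from the control mean, in control SDs;
* an empirical p-value ``p_emp = (r + 1) / (n + 1)`` where ``r`` is the number
  of permutation individuals whose count is at least the proband's count;
* an exact (Clopper-Pearson) upper confidence bound on that probability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "ScreenConfig",
    "AberrantCall",
    "FilterReport",
    "PseudoprobandResult",
    "read_beta_table",
    "read_annotation_table",
    "read_replicate_map",
    "average_replicates",
    "filter_probes",
    "flag_ineligible_controls",
    "delta_beta",
    "pseudoproband_counts",
    "sd_distance",
    "screen_summary",
    "empirical_pvalue",
    "clopper_pearson_upper",
    "run_screen",
    "write_screen_outputs",
]

MISSING_TOKEN = "NA"


class BetaFormatError(ValueError):
    """Raised for malformed beta-matrix input files."""


class BetaValidationError(ValueError):
    """Raised when beta values or identifiers violate matrix invariants."""


@dataclass(frozen=True)
class BetaMatrix:
    """Probes x samples table of beta values.

    Wraps a :class:`pandas.DataFrame` with probe ids as the index and sample
    ids as columns.  All non-missing entries must lie in [0, 1]; missing
    values are ``NaN``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise BetaValidationError(f"duplicate probe ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise BetaValidationError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy(dtype=float)
        bad = np.nonzero((values < 0.0) | (values > 1.0))
        if bad[0].size:
            p, s = bad[0][0], bad[1][0]
            raise BetaValidationError(
                f"beta value {values[p, s]!r} out of [0, 1] at probe "
                f"{df.index[p]!r}, sample {df.columns[s]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV with ``NA`` marking missing cells."""
        out = self.data.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.6g")


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the pseudoproband screen.

    delta_threshold
        minimum |delta beta| for an aberrant call (beta units, default 0.3).
    exclude_chromosomes
        chromosomes removed before screening (default X and Y, to avoid
        confounding by X-inactivation).
    exclude_imprinted
        drop probes flagged as associated with known imprinted genes.
    control_ids
        samples whose counts define the control mean/SD.
    confidence
        two-sided level of the Clopper-Pearson interval.
    """

    delta_threshold: float = 0.3
    exclude_chromosomes: frozenset[str] = frozenset({"X", "Y"})
    exclude_imprinted: bool = True
    control_ids: tuple[str, ...] = ()
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_threshold <= 1.0:
            raise ValueError(f"delta_threshold must be in (0, 1]: {self.delta_threshold}")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError(f"confidence must be in (0, 1): {self.confidence}")


@dataclass(frozen=True)
class AberrantCall:
    """One probe called aberrant in one pseudoproband."""

    probe_id: str
    sample_id: str
    delta: float  # signed: sample beta minus mean of all other samples
    direction: str  # "hypo" if delta < 0 else "hyper"


@dataclass(frozen=True)
class FilterReport:
    """Probes removed per filter stage, in application order."""

    sex_chromosome: tuple[str, ...] = ()
    imprinted: tuple[str, ...] = ()
    missing: tuple[str, ...] = ()
    unannotated_retained: tuple[str, ...] = ()

    @property
    def counts(self) -> dict[str, int]:
        return {
            "sex_chromosome": len(self.sex_chromosome),
            "imprinted": len(self.imprinted),
            "missing": len(self.missing),
            "unannotated_retained": len(self.unannotated_retained),
        }


@dataclass(frozen=True)
class PseudoprobandResult:
    """Counts, calls and (once filled) screen summary statistics."""

    counts: dict[str, int]
    calls: tuple[AberrantCall, ...]
    proband: str | None = None
    control_mean: float | None = None
    control_sd: float | None = None
    n_sds: float | None = None
    r: int | None = None
    n_perm: int | None = None
    p_emp: float | None = None
    ci_upper: float | None = None


# ---------------------------------------------------------------------------
# I/O


def read_beta_table(path: str | Path) -> BetaMatrix:
    """Read a probes x samples beta TSV (first column probe ids, ``NA`` missing)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise BetaFormatError(f"beta table {path}: header needs probe id + samples")
    sample_header = header[1:]
    if len(set(sample_header)) != len(sample_header):
        dup = next(s for s in sample_header if sample_header.count(s) > 1)
        raise BetaValidationError(f"duplicate sample id in header: {dup!r}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=[MISSING_TOKEN],
            keep_default_na=False,
            dtype=str,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise BetaFormatError(f"cannot parse beta table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise BetaFormatError(f"beta table {path} has no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise BetaFormatError(f"non-numeric beta cell in {path}: {exc}") from exc
    return BetaMatrix(values)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation TSV (probe_id, chromosome, gene_symbol, imprinted).

    ``imprinted`` is parsed as 0/1.  Returns a DataFrame indexed by probe_id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "chromosome", "imprinted"}
    missing = required - set(df.columns)
    if missing:
        raise BetaFormatError(f"annotation {path} lacks columns: {sorted(missing)}")
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = ""
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise BetaValidationError(f"probe {dup!r} annotated more than once")
    df = df.set_index("probe_id")
    df["imprinted"] = df["imprinted"].map({"0": False, "1": True, "True": True, "False": False})
    if df["imprinted"].isna().any():
        raise BetaFormatError(f"annotation {path}: imprinted column must be 0/1")
    return df


def read_replicate_map(path: str | Path) -> dict[str, str]:
    """Read a replicate-map TSV with columns sample_id, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise BetaFormatError(f"replicate map {path} needs sample_id and group columns")
    return dict(zip(df["sample_id"], df["group"]))


# ---------------------------------------------------------------------------
# Matrix preparation


def average_replicates(m: BetaMatrix, replicate_map: Mapping[str, str]) -> BetaMatrix:
    """Collapse technical replicates to one column per group.

    Per probe the merged beta is the arithmetic mean over the group's
    non-missing replicate values; a probe missing in every replicate stays
    missing.  Samples not named in the map pass through unchanged.  The merged
    column takes the position of the group's first member.
    """
    absent = [s for s in replicate_map if s not in m.data.columns]
    if absent:
        raise BetaValidationError(f"replicate samples not in matrix: {absent}")
    groups: dict[str, list[str]] = {}
    for sample, group in replicate_map.items():
        groups.setdefault(group, []).append(sample)
    for group, members in groups.items():
        if not members:
            raise BetaValidationError(f"replicate group {group!r} has no samples")

    columns: dict[str, pd.Series] = {}
    seen_groups: set[str] = set()
    for sample in m.data.columns:
        if sample in replicate_map:
            group = replicate_map[sample]
            if group in seen_groups:
                continue
            seen_groups.add(group)
            columns[group] = m.data[groups[group]].mean(axis=1, skipna=True)
        else:
            columns[sample] = m.data[sample]
    return BetaMatrix(pd.DataFrame(columns, index=m.data.index))


def filter_probes(
    m: BetaMatrix, annotation: pd.DataFrame, cfg: ScreenConfig
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the pre-screen probe filters.

    Removes, in order: probes on excluded chromosomes (default X/Y), probes
    flagged imprinted (when configured), and probes with any missing beta
    across samples (listwise, so reference means stay comparable between
    pseudoprobands).  Probes without an annotation row are retained with a
    warning rather than dropped.
    """
    df = m.data
    ann = annotation.reindex(df.index)
    unannotated = tuple(df.index[ann["chromosome"].isna()])
    if unannotated:
        logger.warning(
            "%d probes lack annotation and are retained (e.g. %s)",
            len(unannotated),
            list(unannotated[:3]),
        )

    chrom = ann["chromosome"].astype(object)
    sex_mask = chrom.isin(cfg.exclude_chromosomes).to_numpy()
    sex_removed = tuple(df.index[sex_mask])
    df = df.loc[~sex_mask]

    imprinted_removed: tuple[str, ...] = ()
    if cfg.exclude_imprinted:
        imp = (ann["imprinted"].reindex(df.index) == True).to_numpy()  # noqa: E712
        imprinted_removed = tuple(df.index[imp])
        df = df.loc[~imp]

    miss = df.isna().any(axis=1).to_numpy()
    missing_removed = tuple(df.index[miss])
    df = df.loc[~miss]

    if df.shape[0] == 0:
        raise BetaValidationError("all probes removed by filtering; nothing to screen")
    report = FilterReport(
        sex_chromosome=sex_removed,
        imprinted=imprinted_removed,
        missing=missing_removed,
        unannotated_retained=unannotated,
    )
    return BetaMatrix(df), report


def flag_ineligible_controls(
    m: BetaMatrix,
    annotation: pd.DataFrame,
    cfg: ScreenConfig,
    max_imprinted_hits: int = 1,
) -> list[str]:
    """Optional control pre-screen on imprinted probes.

    Re-runs the pseudoproband counting *without* the imprinted-gene exclusion
    and flags controls showing aberrant methylation at more than
    ``max_imprinted_hits`` imprinted CpGs.  Returns the flagged sample ids.
    """
    pre_cfg = replace(cfg, exclude_imprinted=False)
    filtered, _ = filter_probes(m, annotation, pre_cfg)
    res = pseudoproband_counts(filtered, pre_cfg)
    imprinted_probes = set(annotation.index[annotation["imprinted"].astype(bool)])
    hits: dict[str, int] = {s: 0 for s in filtered.sample_ids}
    for call in res.calls:
        if call.probe_id in imprinted_probes:
            hits[call.sample_id] += 1
    return [s for s in cfg.control_ids if hits.get(s, 0) > max_imprinted_hits]


# ---------------------------------------------------------------------------
# Core screen


def delta_beta(m: BetaMatrix, sample_id: str) -> pd.Series:
    """Signed delta beta of one pseudoproband at every probe.

    ``delta[p] = beta[p, sample] - mean(beta[p, all other samples])``; the
    pseudoproband is excluded from its own reference mean.
    """
    if sample_id not in m.data.columns:
        raise BetaValidationError(f"sample {sample_id!r} not in matrix")
    others = m.data.drop(columns=sample_id)
    if others.shape[1] < 2:
        raise BetaValidationError(
            f"need at least 2 reference samples, have {others.shape[1]}"
        )
    return m.data[sample_id] - others.mean(axis=1, skipna=True)


def pseudoproband_counts(m: BetaMatrix, cfg: ScreenConfig) -> PseudoprobandResult:
    """Assign every sample in turn as pseudoproband and count aberrant probes.

    A probe is aberrant for sample ``s`` when ``|delta_beta(m, s)[p]|`` meets
    ``cfg.delta_threshold``.  Emits one :class:`AberrantCall` per hit; the
    result is invariant under any reordering of rows or columns.
    """
    if m.n_samples < 3:
        raise BetaValidationError("pseudoproband screen needs at least 3 samples")
    values = m.data.to_numpy(dtype=float)
    n = m.n_samples
    row_sum = np.nansum(values, axis=1, keepdims=True)
    # leave-one-out mean of the other columns (no missing cells post-filter)
    ref_mean = (row_sum - values) / (n - 1)
    deltas = values - ref_mean

    counts: dict[str, int] = {}
    calls: list[AberrantCall] = []
    probe_ids = m.probe_ids
    for j, sample in enumerate(m.sample_ids):
        col = deltas[:, j]
        hit = np.abs(col) >= cfg.delta_threshold
        hit &= ~np.isnan(col)
        counts[sample] = int(hit.sum())
        for i in np.nonzero(hit)[0]:
            d = float(col[i])
            calls.append(
                AberrantCall(
                    probe_id=probe_ids[i],
                    sample_id=sample,
                    delta=d,
                    direction="hypo" if d < 0 else "hyper",
                )
            )
    return PseudoprobandResult(counts=counts, calls=tuple(calls))


def sd_distance(count: float, control_mean: float, control_sd: float) -> float:
    """Distance of a count from the control mean, in control SDs."""
    if control_sd == 0.0:
        return math.nan
    return (count - control_mean) / control_sd


def screen_summary(
    res: PseudoprobandResult, proband: str, cfg: ScreenConfig
) -> PseudoprobandResult:
    """Fill control mean/SD and the proband's SD distance.

    The control SD uses the n-1 (sample) denominator.  A zero control SD
    yields ``n_sds = nan`` with a warning instead of an exception.
    """
    if proband in cfg.control_ids:
        raise BetaValidationError(f"proband {proband!r} must not be a control")
    if len(cfg.control_ids) < 2:
        raise BetaValidationError("need at least 2 controls for mean/SD")
    missing = [s for s in cfg.control_ids if s not in res.counts]
    if missing:
        raise BetaValidationError(f"control ids without counts: {missing}")
    control_counts = np.array([res.counts[s] for s in cfg.control_ids], dtype=float)
    control_mean = float(control_counts.mean())
    control_sd = float(control_counts.std(ddof=1))
    if control_sd == 0.0:
        logger.warning("control SD is zero; SD distance is undefined")
    n_sds = sd_distance(res.counts[proband], control_mean, control_sd)
    return replace(
        res,
        proband=proband,
        control_mean=control_mean,
        control_sd=control_sd,
        n_sds=n_sds,
    )


def empirical_pvalue(
    res: PseudoprobandResult, proband: str, perm_ids: Iterable[str]
) -> tuple[int, int, float]:
    """Empirical p-value of the proband's count under the permutation scheme.

    ``r`` counts permutation individuals with an aberrant-CpG count greater
    than or equal to the proband's (ties included); ``p_emp = (r+1)/(n+1)``.
    """
    perm_ids = list(perm_ids)
    if not perm_ids:
        raise BetaValidationError("permutation set is empty")
    if proband in perm_ids:
        raise BetaValidationError(f"proband {proband!r} must not be in the permutation set")
    missing = [s for s in perm_ids if s not in res.counts]
    if missing:
        raise BetaValidationError(f"permutation ids without counts: {missing}")
    observed = res.counts[proband]
    r = sum(1 for s in perm_ids if res.counts[s] >= observed)
    n_perm = len(perm_ids)
    return r, n_perm, (r + 1) / (n_perm + 1)


def clopper_pearson_upper(x: int, n: int, conf: float = 0.95) -> float:
    """Exact two-sided upper confidence limit for a binomial proportion.

    The Clopper-Pearson upper bound is the ``1 - (1-conf)/2`` quantile of the
    Beta(x+1, n-x) distribution; for ``x = n`` it is 1, and for ``x = 0`` it
    reduces to ``1 - ((1-conf)/2)**(1/n)``.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"invalid binomial counts x={x}, n={n}")
    if not 0.0 < conf < 1.0:
        raise ValueError(f"confidence must be in (0, 1): {conf}")
    if x == n:
        return 1.0
    alpha = 1.0 - conf
    return float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))


# ---------------------------------------------------------------------------
# Orchestration


def run_screen(
    m: BetaMatrix,
    annotation: pd.DataFrame,
    proband: str,
    cfg: ScreenConfig,
    perm_ids: Sequence[str] | None = None,
    replicate_map: Mapping[str, str] | None = None,
) -> tuple[PseudoprobandResult, FilterReport]:
    """Full screen: replicate averaging, filtering, counting, statistics.

    ``perm_ids`` defaults to the configured controls; it is explicit because
    the permutation set need not coincide with the samples entering the
    control mean/SD.
    """
    if replicate_map:
        m = average_replicates(m, replicate_map)
    filtered, report = filter_probes(m, annotation, cfg)
    res = pseudoproband_counts(filtered, cfg)
    res = screen_summary(res, proband, cfg)
    ids = list(perm_ids) if perm_ids is not None else list(cfg.control_ids)
    r, n_perm, p_emp = empirical_pvalue(res, proband, ids)
    ci = clopper_pearson_upper(r, n_perm, cfg.confidence)
    res = replace(res, r=r, n_perm=n_perm, p_emp=p_emp, ci_upper=ci)
    return res, report


def write_screen_outputs(
    res: PseudoprobandResult, outdir: str | Path
) -> dict[str, Path]:
    """Write calls, counts and summary TSVs; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": outdir / "calls.tsv",
        "counts": outdir / "counts.tsv",
        "summary": outdir / "summary.tsv",
    }
    pd.DataFrame(
        [(c.probe_id, c.sample_id, c.delta, c.direction) for c in res.calls],
        columns=["probe_id", "sample_id", "delta", "direction"],
    ).to_csv(paths["calls"], sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        sorted(res.counts.items()), columns=["sample_id", "count"]
    ).to_csv(paths["counts"], sep="\t", index=False)
    summary = pd.DataFrame(
        [
            {
                "proband": res.proband,
                "proband_count": res.counts.get(res.proband) if res.proband else None,
                "control_mean": res.control_mean,
                "control_sd": res.control_sd,
                "n_sds": res.n_sds,
                "r": res.r,
                "n_perm": res.n_perm,
                "p_emp": res.p_emp,
                "ci_upper": res.ci_upper,
            }
        ]
    )
    summary.to_csv(paths["summary"], sep="\t", index=False, float_format="%.6g")
    return paths
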