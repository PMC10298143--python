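"""Donor-level statistics on allele-frequency matrices.

The workhorse is a per-variant one-way fixed-effects ANOVA of allele
frequency on donor identity (equivalent to a linear model with a single
categorical predictor; for two donors F equals the pooled-variance t²).
On top of it sit:

* :func:`select_variable_sites` — top-n variants by AF variance;
* :func:`informative_variants` — variants separating donors at an
  extreme raw-p threshold (default 1e-100);
* :func:`discriminative_germline` — variants fixed (mean AF > 0.9) in
  exactly one donor, i.e. personal homoplasmic markers;
* :func:`heteroplasmy_scan` — after excluding germline markers, variants
  whose donor mean AF sits in an intermediate band (default 1%–25%) and
  differs significantly across donors.

Missing AF entries (no coverage) are dropped from every statistic, never
imputed. p-values are kept in log10 space internally so that thresholds
far below double-precision underflow (the 1e-100 regime) compare exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allele_matrices import AlleleFrequencyMatrix, CoverageMatrix
from .reference_io import Variant

_LN10 = math.log(10.0)
# relative tolerance distinguishing a genuinely zero sum of squares from
# floating-point residue of the centering subtraction
_SS_RTOL = 1e-12


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds of the statistical layer (defaults follow the method's
    published values where stated).

    n_variable_sites: how many top-variance sites to keep.
    germline_af_threshold: donor mean AF above which a variant is a
        fixed personal marker.
    anova_p_threshold: raw p cutoff for informative variants.
    het_lo / het_hi: open interval of donor mean AF called heteroplasmic.
    min_cells_per_group: non-missing cells a donor needs to enter a test.
    min_covered_cells: non-missing cells a variant needs for the
        variance ranking.
    """

    n_variable_sites: int = 500
    germline_af_threshold: float = 0.9
    anova_p_threshold: float = 1e-100
    het_lo: float = 0.01
    het_hi: float = 0.25
    min_cells_per_group: int = 2
    min_covered_cells: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.het_lo < self.het_hi < self.germline_af_threshold <= 1):
            raise ValueError(
                "need 0 < het_lo < het_hi < germline_af_threshold <= 1"
            )
        if self.n_variable_sites < 1:
            raise ValueError("n_variable_sites must be >= 1")


@dataclass
class DonorLabels:
    """cell_id → donor_id assignment; unlabeled cells are excluded."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) < 2:
            raise ValueError("need at least 2 donors")

    @property
    def donors(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def cells_of(self, donor: str) -> list[str]:
        return [c for c, d in self.mapping.items() if d == donor]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DonorLabels":
        """Read a labels table: columns ``cell_id`` and ``donor_id``, header required."""
        tab = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("cell_id", "donor_id"):
            if col not in tab.columns:
                raise ValueError(f"labels file {path} lacks required column {col!r}")
        if tab["cell_id"].duplicated().any():
            raise ValueError(f"labels file {path} has duplicate cell ids")
        return cls(mapping=dict(zip(tab["cell_id"], tab["donor_id"])))


@dataclass
class SiteTestResult:
    """One-way ANOVA of AF on donor for a single variant."""

    variant: Variant | None
    F: float
    p: float
    log10_p: float
    df_between: int
    df_within: int
    group_means: dict[str, float]
    group_n: dict[str, int]

    @property
    def testable(self) -> bool:
        return self.df_between >= 1 and self.df_within >= 1


@dataclass
class HeteroplasmyCall:
    """A variant with intermediate donor-level AF in at least one donor."""

    variant: Variant
    carriers: list[str]
    donor_means: dict[str, float]
    result: SiteTestResult
    p_adjusted: float


def _columns_by_donor(
    cell_ids: Sequence[str], labels: DonorLabels
) -> dict[str, np.ndarray]:
    known = set(cell_ids)
    unknown = [c for c in labels.mapping if c not in known]
    if unknown:
        raise ValueError(
            f"{len(unknown)} labeled cells absent from the matrix "
            f"(first: {unknown[:5]})"
        )
    col = {c: i for i, c in enumerate(cell_ids)}
    return {
        d: np.array([col[c] for c in labels.cells_of(d)], dtype=np.int64)
        for d in labels.donors
    }


def _anova_arrays(
    values: np.ndarray, cols_by_donor: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Vectorised one-way ANOVA over the rows of ``values`` (V × cells).

    Returns per-row F, p, log10_p, dfs and per-donor n / mean stacked
    as (D, V) arrays. Rows are computed from group sums; groups with no
    non-missing value at a row simply drop out of that row's test.
    """
    donors = list(cols_by_donor)
    V = values.shape[0]
    D = len(donors)
    n = np.zeros((D, V), dtype=np.int64)
    s = np.zeros((D, V))
    ss = np.zeros((D, V))
    for k, d in enumerate(donors):
        X = values[:, cols_by_donor[d]]
        ok = ~np.isnan(X)
        n[k] = ok.sum(axis=1)
        Xz = np.where(ok, X, 0.0)
        s[k] = Xz.sum(axis=1)
        ss[k] = (Xz * Xz).sum(axis=1)
    N = n.sum(axis=0)
    S = s.sum(axis=0)
    SS = ss.sum(axis=0)
    G1 = (n >= 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        grand = np.where(N > 0, S * S / np.maximum(N, 1), 0.0)
        ssb = np.where(n > 0, s * s / np.maximum(n, 1), 0.0).sum(axis=0) - grand
        sst = SS - grand
    ssw = sst - ssb
    tol = _SS_RTOL * np.maximum(SS, 1.0)
    ssb = np.where(ssb < tol, np.maximum(ssb, 0.0), ssb)
    ssw = np.where(ssw < tol, np.maximum(ssw, 0.0), ssw)
    df_b = G1 - 1
    df_w = N - G1
    valid = (df_b >= 1) & (df_w >= 1)
    F = np.full(V, np.nan)
    p = np.full(V, np.nan)
    log10_p = np.full(V, np.nan)
    zero_w = ssw <= tol
    zero_b = ssb <= tol
    both = valid & zero_w & zero_b
    F[both], p[both], log10_p[both] = 0.0, 1.0, 0.0
    infin = valid & zero_w & ~zero_b
    F[infin], p[infin], log10_p[infin] = np.inf, 0.0, -np.inf
    reg = valid & ~zero_w
    if reg.any():
        Freg = (ssb[reg] / df_b[reg]) / (ssw[reg] / df_w[reg])
        F[reg] = Freg
        p[reg] = stats.f.sf(Freg, df_b[reg], df_w[reg])
        log10_p[reg] = stats.f.logsf(Freg, df_b[reg], df_w[reg]) / _LN10
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return {
        "donors": donors,
        "F": F,
        "p": p,
        "log10_p": log10_p,
        "df_between": df_b,
        "df_within": df_w,
        "valid": valid,
        "n": n,
        "means": means,
    }


def _result_from_arrays(
    tab: dict, i: int, variant: Variant | None
) -> SiteTestResult:
    donors = tab["donors"]
    return SiteTestResult(
        variant=variant,
        F=float(tab["F"][i]),
        p=float(tab["p"][i]),
        log10_p=float(tab["log10_p"][i]),
        df_between=int(tab["df_between"][i]),
        df_within=int(tab["df_within"][i]),
        group_means={d: float(tab["means"][k, i]) for k, d in enumerate(donors)},
        group_n={d: int(tab["n"][k, i]) for k, d in enumerate(donors)},
    )


def site_anova(
    af_row: "pd.Series | Mapping[str, float]",
    labels: DonorLabels,
    min_cells_per_group: int = 2,
) -> SiteTestResult:
    """One-way ANOVA of a single variant's AF across donors.

    ``af_row`` maps cell_id → AF (NaN = missing), e.g. the output of
    :meth:`AlleleFrequencyMatrix.row`. Raises when fewer than two donors
    have ``min_cells_per_group`` non-missing cells.
    """
    row = pd.Series(af_row, dtype=float)
    cols = _columns_by_donor(list(row.index), labels)
    tab = _anova_arrays(row.to_numpy()[None, :], cols)
    enough = (tab["n"][:, 0] >= min_cells_per_group).sum()
    if enough < 2 or not tab["valid"][0]:
        raise ValueError(
            f"untestable site: only {enough} donors with >= "
            f"{min_cells_per_group} covered cells"
        )
    return _result_from_arrays(tab, 0, None)


def anova_table(
    af: AlleleFrequencyMatrix,
    labels: DonorLabels,
    min_cells_per_group: int = 2,
) -> pd.DataFrame:
    """Genome-wide per-variant ANOVA as a tidy table.

    Columns: label/position/ref/alt, F, p, log10_p, dfs, testable, and
    per-donor ``mean_<donor>`` / ``n_<donor>``. Untestable variants get
    NaN statistics and ``testable=False`` rather than raising.
    """
    cols = _columns_by_donor(af.cell_ids, labels)
    tab = _anova_arrays(af.values, cols)
    enough = (tab["n"] >= min_cells_per_group).sum(axis=0)
    testable = tab["valid"] & (enough >= 2)
    out = pd.DataFrame(
        {
            "label": [v.label for v in af.variants],
            "position": [v.position for v in af.variants],
            "ref": [v.ref for v in af.variants],
            "alt": [v.alt for v in af.variants],
            "F": tab["F"],
            "p": tab["p"],
            "log10_p": tab["log10_p"],
            "df_between": tab["df_between"],
            "df_within": tab["df_within"],
            "testable": testable,
        }
    )
    for k, d in enumerate(tab["donors"]):
        out[f"mean_{d}"] = tab["means"][k]
        out[f"n_{d}"] = tab["n"][k]
    return out


def select_variable_sites(
    af: AlleleFrequencyMatrix,
    n: int = 500,
    min_covered_cells: int = 10,
) -> list[Variant]:
    """The n most highly variable variant sites by AF sample variance.

    Variance is the unbiased sample variance over non-missing cells;
    variants covered in fewer than ``min_covered_cells`` cells (or fewer
    than 2) are ineligible. Ties break by position then alt base.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = (~np.isnan(af.values)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.full(af.values.shape[0], np.nan)
        ok = counts >= max(min_covered_cells, 2)
        if ok.any():
            var[ok] = np.nanvar(af.values[ok], axis=1, ddof=1)
    eligible = np.flatnonzero(ok)
    if eligible.size == 0:
        raise ValueError(
            f"no variant covered in >= {min_covered_cells} cells"
        )
    order = sorted(
        eligible,
        key=lambda i: (-var[i], af.variants[i].position, af.variants[i].alt),
    )
    return [af.variants[i] for i in order[:n]]


def donor_mean_af(
    af: AlleleFrequencyMatrix,
    labels: DonorLabels,
    cov: CoverageMatrix | None = None,
    mode: str = "cell_mean",
) -> pd.DataFrame:
    """Per-donor average AF per variant (variants × donors).

    ``cell_mean`` (default) is the unweighted mean over cells with
    non-missing AF — the literal per-individual average. ``pseudobulk``
    pools reads instead (Σalt/Σcov over covered cells) and requires the
    coverage matrix; it is robust to uneven depth across cells.
    """
    cols = _columns_by_donor(af.cell_ids, labels)
    data = {}
    if mode == "cell_mean":
        for d, idx in cols.items():
            X = af.values[:, idx]
            ok = ~np.isnan(X)
            n = ok.sum(axis=1)
            s = np.where(ok, X, 0.0).sum(axis=1)
            with np.errstate(invalid="ignore"):
                data[d] = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    elif mode == "pseudobulk":
        if cov is None:
            raise ValueError("pseudobulk mode needs the coverage matrix")
        pos_idx = np.array([v.position - 1 for v in af.variants], dtype=np.int64)
        cov_dense = np.asarray(cov.X.todense(), dtype=np.float64)[pos_idx, :]
        alt_dense = np.where(np.isnan(af.values), 0.0, af.values) * np.where(
            np.isnan(af.values), 0.0, cov_dense
        )
        cov_dense = np.where(np.isnan(af.values), 0.0, cov_dense)
        for d, idx in cols.items():
            num = alt_dense[:, idx].sum(axis=1)
            den = cov_dense[:, idx].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                data[d] = np.where(den > 0, num / den, np.nan)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(data, index=[v.label for v in af.variants])


def _log10_threshold(p_threshold: float) -> float:
    return math.log10(p_threshold) if p_threshold > 0 else -math.inf


def informative_variants(
    af: AlleleFrequencyMatrix,
    labels: DonorLabels,
    params: AnalysisParams | None = None,
) -> list[SiteTestResult]:
    """Variants whose AF differs across donors at the raw-p threshold.

    Returns testable variants with p < ``params.anova_p_threshold``
    (compared in log10 space), sorted by p ascending then position/alt.
    A threshold >= 1 returns every testable variant.
    """
    params = params or AnalysisParams()
    cols = _columns_by_donor(af.cell_ids, labels)
    tab = _anova_arrays(af.values, cols)
    enough = (tab["n"] >= params.min_cells_per_group).sum(axis=0)
    testable = tab["valid"] & (enough >= 2)
    if params.anova_p_threshold >= 1.0:
        hits = np.flatnonzero(testable)
    else:
        cut = _log10_threshold(params.anova_p_threshold)
        hits = np.flatnonzero(testable & (tab["log10_p"] < cut))
    order = sorted(
        hits,
        key=lambda i: (
            tab["log10_p"][i],
            af.variants[i].position,
            af.variants[i].alt,
        ),
    )
    return [_result_from_arrays(tab, i, af.variants[i]) for i in order]


def discriminative_germline(
    af: AlleleFrequencyMatrix,
    labels: DonorLabels,
    params: AnalysisParams | None = None,
    mean_mode: str = "cell_mean",
    cov: CoverageMatrix | None = None,
) -> list[tuple[SiteTestResult, str]]:
    """Personal fixed variants: mean AF above the germline threshold in
    exactly one donor, every other donor at or below it.

    Only variants testable by ANOVA are considered; output is sorted by
    ANOVA p ascending (position/alt on ties) and annotated with the
    carrier donor.
    """
    params = params or AnalysisParams()
    means = donor_mean_af(af, labels, cov=cov, mode=mean_mode)
    above = (means.to_numpy() > params.germline_af_threshold)
    # NaN means (donor never covered) compare False, i.e. not above
    one_carrier = above.sum(axis=1) == 1
    cols = _columns_by_donor(af.cell_ids, labels)
    tab = _anova_arrays(af.values, cols)
    enough = (tab["n"] >= params.min_cells_per_group).sum(axis=0)
    testable = tab["valid"] & (enough >= 2)
    hits = np.flatnonzero(one_carrier & testable)
    donor_names = list(means.columns)
    order = sorted(
        hits,
        key=lambda i: (
            tab["log10_p"][i],
            af.variants[i].position,
            af.variants[i].alt,
        ),
    )
    out = []
    for i in order:
        carrier = donor_names[int(np.flatnonzero(above[i])[0])]
        out.append((_result_from_arrays(tab, i, af.variants[i]), carrier))
    return out


def heteroplasmy_scan(
    af: AlleleFrequencyMatrix,
    cov: CoverageMatrix,
    labels: DonorLabels,
    params: AnalysisParams | None = None,
    significance: float = 0.05,
    exclude: str = "germline",
    mean_mode: str = "cell_mean",
) -> list[HeteroplasmyCall]:
    """Donor-specific intermediate-frequency variants.

    Pipeline: (1) drop the discriminative-germline set (or, with
    ``exclude='informative'``, every variant passing the extreme raw-p
    cut); (2) keep variants where at least one donor's mean AF lies
    strictly inside (het_lo, het_hi); (3) keep those significant by
    per-variant ANOVA at a Bonferroni-adjusted ``significance`` over the
    banded variants. Carriers are the donors whose mean AF is in band.
    """
    params = params or AnalysisParams()
    if exclude == "germline":
        excluded = {
            r.variant for r, _ in discriminative_germline(
                af, labels, params, mean_mode=mean_mode, cov=cov
            )
        }
    elif exclude == "informative":
        excluded = {r.variant for r in informative_variants(af, labels, params)}
    else:
        raise ValueError(f"unknown exclude policy {exclude!r}")
    means = donor_mean_af(af, labels, cov=cov, mode=mean_mode)
    M = means.to_numpy()
    with np.errstate(invalid="ignore"):
        in_band = (M > params.het_lo) & (M < params.het_hi)
    banded = np.flatnonzero(in_band.any(axis=1))
    banded = [i for i in banded if af.variants[i] not in excluded]
    if not banded:
        return []
    cols = _columns_by_donor(af.cell_ids, labels)
    tab = _anova_arrays(af.values, cols)
    enough = (tab["n"] >= params.min_cells_per_group).sum(axis=0)
    testable = tab["valid"] & (enough >= 2)
    tested = [i for i in banded if testable[i]]
    if not tested:
        return []
    cut = _log10_threshold(significance / len(tested))
    donor_names = list(means.columns)
    calls: list[HeteroplasmyCall] = []
    for i in sorted(
        tested,
        key=lambda i: (tab["log10_p"][i], af.variants[i].position, af.variants[i].alt),
    ):
        if not tab["log10_p"][i] < cut:
            continue
        carriers = [donor_names[k] for k in np.flatnonzero(in_band[i])]
        p_adj = min(1.0, float(tab["p"][i]) * len(tested))
        calls.append(
            HeteroplasmyCall(
                variant=af.variants[i],
                carriers=carriers,
                donor_means={d: float(M[i, k]) for k, d in enumerate(donor_names)},
                result=_result_from_arrays(tab, i, af.variants[i]),
                p_adjusted=p_adj,
            )
        )
    return calls


def results_to_frame(
    results: "Sequence[SiteTestResult] | Sequence[tuple[SiteTestResult, str]] | Sequence[HeteroplasmyCall]",
) -> pd.DataFrame:
    """Flatten result objects into a ranked report table."""
    rows = []
    for item in results:
        carrier = None
        p_adj = None
        if isinstance(item, HeteroplasmyCall):
            r = item.result
            carrier = ",".join(item.carriers)
            p_adj = item.p_adjusted
        elif isinstance(item, tuple):
            r, carrier = item
        else:
            r = item
        row = {
            "label": r.variant.label if r.variant else "",
            "position": r.variant.position if r.variant else np.nan,
            "ref": r.variant.ref if r.variant else "",
            "alt": r.variant.alt if r.variant else "",
            "F": r.F,
            "p": r.p,
            "log10_p": r.log10_p,
            "df_between": r.df_between,
            "df_within": r.df_within,
        }
        for d, m in r.group_means.items():
            row[f"mean_{d}"] = m
        for d, k in r.group_n.items():
            row[f"n_{d}"] = k
        if carrier is not None:
            row["carrier"] = carrier
        if p_adj is not None:
            row["p_adjusted"] = p_adj
        rows.append(row)
    return pd.DataFrame(rows)
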