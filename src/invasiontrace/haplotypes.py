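"""Chloroplast-SSR haplotype calling and per-population frequency analysis.

Chloroplast microsatellites (cpSSR) are uniparentally inherited, so the
ordered combination of allele sizes at the retained plastid loci (by
default ccmp3 and ccmp4) defines a plastid haplotype, labelled by
hyphen-joined sizes, e.g. ``"122-121"``.  Frequencies are tabulated per
sampled population; populations carry a region label (``native`` for the
species' home range, ``invaded`` elsewhere), and a population in which all
sampled individuals share one haplotype is called monomorphic.  Contrasts
such as a haplotype present in many invaded-range populations but absent
from the native range are the signal of interest: under a single
introduction from one source, invaded-range plastid diversity should be
minimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LOCI",
    "call_haplotypes",
    "frequency_table",
    "HaplotypeFrequencyTable",
    "haplotype_summary",
    "region_contrast",
    "load_builtin_frequencies",
]

DEFAULT_LOCI = ("ccmp3", "ccmp4")
REGIONS = ("native", "invaded")


@dataclass
class HaplotypeCalls:
    """Per-individual haplotype labels plus the exclusion report."""

    calls: pd.DataFrame  # individual_id, population_id, region, haplotype
    excluded: pd.DataFrame  # individual_id, population_id, missing_loci
    loci: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.calls)


def call_haplotypes(genotypes: pd.DataFrame, loci=DEFAULT_LOCI) -> HaplotypeCalls:
    """Call multilocus haplotypes as ordered allele-size tuples.

    `genotypes` has one row per individual with columns ``individual_id``,
    ``population_id``, ``region`` and one integer allele-size column per
    locus (NaN = missing).  Individuals missing any chosen locus are
    excluded and listed in the returned report.
    """
    loci = tuple(loci)
    unknown = [l for l in loci if l not in genotypes.columns]
    if unknown:
        raise ValueError(f"unknown locus/loci: {unknown}")
    alleles = genotypes[list(loci)].apply(pd.to_numeric, errors="coerce")
    ok = alleles.notna().all(axis=1)

    excluded = genotypes.loc[~ok, ["individual_id", "population_id"]].copy()
    miss = alleles.loc[~ok].isna()
    excluded["missing_loci"] = [
        ",".join(l for l in loci if miss.at[idx, l]) for idx in miss.index
    ]
    kept = genotypes.loc[ok, ["individual_id", "population_id"]].copy()
    if "region" in genotypes.columns:
        kept["region"] = genotypes.loc[ok, "region"]
    else:
        kept["region"] = pd.NA
    kept["haplotype"] = (
        alleles.loc[ok].astype(int).astype(str).agg("-".join, axis=1)
    )
    return HaplotypeCalls(calls=kept.reset_index(drop=True), excluded=excluded.reset_index(drop=True), loci=loci)


@dataclass
class HaplotypeFrequencyTable:
    """Populations x haplotypes matrix of percentages.

    ``freq`` is indexed by population, columns are haplotype labels, values
    are percentages at full precision (rounded only on export).  ``n`` is
    the per-population sample size (NaN when the table was built from
    percentages directly), ``region`` the per-population region label.
    """

    freq: pd.DataFrame
    n: pd.Series
    region: pd.Series
    flagged_small: list[str] = field(default_factory=list)

    @property
    def populations(self) -> list[str]:
        return list(self.freq.index)

    @property
    def haplotypes(self) -> list[str]:
        return list(self.freq.columns)

    def row_sums(self) -> pd.Series:
        return self.freq.sum(axis=1)

    def to_dataframe(self, decimals: int | None = 2) -> pd.DataFrame:
        out = self.freq if decimals is None else self.freq.round(decimals)
        out = out.copy()
        out.insert(0, "region", self.region)
        out.insert(1, "n", self.n)
        return out

    def to_csv(self, path: str | Path, decimals: int = 2) -> None:
        self.to_dataframe(decimals).to_csv(path, index_label="population")

    @classmethod
    def from_percentages(cls, df: pd.DataFrame, n: pd.Series | None = None) -> "HaplotypeFrequencyTable":
        """Build from an already-tabulated percentage matrix.

        `df` must carry a ``region`` column; remaining columns are
        haplotype percentages, indexed by population.
        """
        if "region" not in df.columns:
            raise ValueError("percentage table must carry a 'region' column")
        region = df["region"]
        hap_cols = [c for c in df.columns if c not in ("region", "n")]
        freq = df[hap_cols].astype(float)
        if n is None:
            n = df["n"].astype(float) if "n" in df.columns else pd.Series(np.nan, index=df.index)
        return cls(freq=freq, n=n, region=region)


def frequency_table(calls: HaplotypeCalls, min_n: int = 1) -> HaplotypeFrequencyTable:
    """Per-population haplotype percentages (100 * count / n).

    Populations with fewer than `min_n` called individuals are kept but
    flagged on the returned table.
    """
    df = calls.calls
    if df.empty:
        raise ValueError("no called individuals")
    counts = df.pivot_table(index="population_id", columns="haplotype", values="individual_id", aggfunc="count", fill_value=0)
    n = counts.sum(axis=1)
    freq = counts.div(n, axis=0) * 100.0
    region = df.groupby("population_id")["region"].first().reindex(freq.index)
    flagged = list(n.index[n < min_n])
    return HaplotypeFrequencyTable(freq=freq, n=n.astype(float), region=region, flagged_small=flagged)


@dataclass
class HaplotypeSummary:
    """Per-haplotype means/presence and monomorphic-population counts."""

    mean_frequency: pd.Series  # percent, averaged over ALL populations (zeros included)
    sum_frequency: pd.Series  # column sums of the percentage matrix (table checksum)
    presence_count: pd.Series  # populations where frequency > 0
    presence_by_region: pd.DataFrame  # region x haplotype counts
    monomorphic_total: int
    monomorphic_by_region: dict[str, int]
    monomorphic_populations: list[str]
    n_populations: int


def _monomorphic_mask(ft: HaplotypeFrequencyTable, tol: float = 0.05) -> pd.Series:
    # a single haplotype at 100% (within printed-rounding tolerance)
    return (ft.freq.max(axis=1) >= 100.0 - tol) & ((ft.freq > 0).sum(axis=1) == 1)


def haplotype_summary(ft: HaplotypeFrequencyTable) -> HaplotypeSummary:
    """Mean frequency, presence counts and monomorphic populations.

    Means are arithmetic means over *all* populations, absences counting as
    zero — the convention of a percentages table whose MEAN row divides the
    column SUM by the number of populations.
    """
    if len(ft.freq) == 0:
        raise ValueError("frequency table has no populations")
    mono = _monomorphic_mask(ft)
    presence = (ft.freq > 0)
    by_region = presence.groupby(ft.region).sum()
    return HaplotypeSummary(
        mean_frequency=ft.freq.mean(axis=0),
        sum_frequency=ft.freq.sum(axis=0),
        presence_count=presence.sum(axis=0),
        presence_by_region=by_region,
        monomorphic_total=int(mono.sum()),
        monomorphic_by_region={r: int(mono[ft.region == r].sum()) for r in ft.region.dropna().unique()},
        monomorphic_populations=list(ft.freq.index[mono]),
        n_populations=len(ft.freq),
    )


def region_contrast(ft: HaplotypeFrequencyTable) -> pd.DataFrame:
    """Per-haplotype presence and mean frequency split by region.

    Rows are haplotypes; columns give, per region, the number of
    populations where the haplotype is present and its mean percentage
    (zeros included).  Raises if any population lacks a region label.
    """
    missing = list(ft.freq.index[ft.region.isna()])
    if missing:
        raise ValueError(f"population(s) without region label: {missing}")
    rows = {}
    for reg, block in ft.freq.groupby(ft.region):
        rows[(reg, "n_populations")] = pd.Series(len(block), index=ft.freq.columns)
        rows[(reg, "present_in")] = (block > 0).sum(axis=0)
        rows[(reg, "mean_pct")] = block.mean(axis=0)
    out = pd.DataFrame(rows)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["region", "stat"])
    return out


def load_builtin_frequencies() -> HaplotypeFrequencyTable:
    """Bundled per-population cpSSR haplotype percentage table (37 populations,
    5 haplotypes at ccmp3-ccmp4), transcribed from the published survey of
    *Oxalis pes-caprae* with comma decimals normalised to points."""
    from importlib.resources import files

    path = files("invasiontrace.data").joinpath("oxalis_cpssr_frequencies.csv")
    with path.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, index_col="population")
    return HaplotypeFrequencyTable.from_percentages(df)
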