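"""Model/Results interface over the invasion-retracing pipeline.

:class:`InvasionOriginModel` is built from a set of dated occurrence
records and, on :meth:`~InvasionOriginModel.fit`, runs the full analysis at
each requested year cutoff: first-record extraction, silhouette scan over
the number of clusters, K-means partition, per-cluster Rossmo geoprofile
and origin estimate.  The returned :class:`InvasionOriginResults` carries
the estimates and diagnostics and renders a ``summary()`` table.

>>> from invasiontrace import InvasionOriginModel, synthetic
>>> rs, truth, sc = synthetic.reference_invasion()
>>> res = InvasionOriginModel(rs, cutoffs=(1840, 1880, 2010)).fit(seed=1)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterPartition
from .geoprofile import ClusterGeoprofile, GeoprofileParams, cluster_geoprofiles
from .records import RecordSet, filter_until, first_records, read_records, summarize

__all__ = ["InvasionOriginModel", "InvasionOriginResults", "CutoffFit"]


@dataclass
class CutoffFit:
    """Everything fitted at one year cutoff."""

    cutoff: int
    n_records: int
    k: int
    partition: ClusterPartition
    silhouette_profile: pd.DataFrame | None
    clusters: list[ClusterGeoprofile]

    @property
    def mean_silhouette(self) -> float:
        return self.partition.mean_silhouette


class InvasionOriginModel:
    """Infer the number and location of introduction centres of an invasion.

    Parameters
    ----------
    records : RecordSet or DataFrame
        Dated, georeferenced occurrence reports (one per row when a
        DataFrame, with the standard occurrence columns).
    cutoffs : sequence of int
        Strictly increasing year cutoffs; the analysis is repeated on the
        records known up to each cutoff, tracing how the inferred structure
        grew through time.
    k_range : (k_min, k_max)
        Range of cluster numbers scanned by the silhouette criterion;
        k_max=None means min(8, n-1).
    gp_params : GeoprofileParams
        Rossmo surface parameters (buffer, exponents, grid, metric).
    q : float
        Probability mass of the reported top ("red") region per cluster.
    """

    def __init__(
        self,
        records: RecordSet | pd.DataFrame,
        cutoffs=(1840, 1880, 2010),
        k_range: tuple[int, int | None] = (2, None),
        n_restarts: int = 20,
        gp_params: GeoprofileParams | None = None,
        q: float = 0.05,
    ):
        if isinstance(records, pd.DataFrame):
            records = RecordSet.from_dataframe(records)
        self.records = records
        cutoffs = tuple(int(c) for c in cutoffs)
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        self.cutoffs = cutoffs
        self.k_range = k_range
        self.n_restarts = int(n_restarts)
        self.gp_params = gp_params or GeoprofileParams()
        self.q = float(q)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "InvasionOriginModel":
        return cls(read_records(path), **kwargs)

    def fit(self, seed: int = 0) -> "InvasionOriginResults":
        fits = []
        for cutoff in self.cutoffs:
            part, profile, clusters = cluster_geoprofiles(
                self.records,
                cutoff=cutoff,
                k_range=self.k_range,
                seed=seed,
                n_restarts=self.n_restarts,
                gp_params=self.gp_params,
                q=self.q,
            )
            n_rec = len(first_records(filter_until(self.records, cutoff)))
            fits.append(
                CutoffFit(
                    cutoff=cutoff,
                    n_records=n_rec,
                    k=part.k,
                    partition=part,
                    silhouette_profile=profile,
                    clusters=clusters,
                )
            )
        return InvasionOriginResults(model=self, seed=int(seed), fits=fits)


@dataclass
class InvasionOriginResults:
    """Fitted introduction-centre estimates across year cutoffs."""

    model: InvasionOriginModel
    seed: int
    fits: list[CutoffFit] = field(default_factory=list)

    def __getitem__(self, cutoff: int) -> CutoffFit:
        for f in self.fits:
            if f.cutoff == cutoff:
                return f
        raise KeyError(cutoff)

    @property
    def k_by_cutoff(self) -> dict[int, int]:
        return {f.cutoff: f.k for f in self.fits}

    def origins_table(self) -> pd.DataFrame:
        """One row per (cutoff, cluster): size, silhouette, peak, red-region size."""
        rows = []
        for f in self.fits:
            sizes = f.partition.sizes()
            for cg in f.clusters:
                lon, lat = cg.origin.peak_lonlat
                rows.append(
                    {
                        "cutoff": f.cutoff,
                        "cluster": cg.cluster_id,
                        "n_points": int(sizes[cg.cluster_id]),
                        "peak_lon": round(lon, 4),
                        "peak_lat": round(lat, 4),
                        "top_region_cells": cg.origin.n_cells,
                        "top_region_q": cg.origin.q,
                        "buffer": round(cg.geoprofile.buffer_used, 3),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Invasion origin analysis",
            "=" * 72,
            f"records: {len(self.model.records)}   seed: {self.seed}   "
            f"restarts: {self.model.n_restarts}   metric: {self.model.gp_params.distance_metric}",
            "",
            "Cluster-number selection (mean silhouette width)",
            "-" * 72,
        ]
        for f in self.fits:
            prof = ""
            if f.silhouette_profile is not None:
                prof = "  ".join(
                    f"k={int(r.k)}:{r.mean_silhouette:.3f}" for r in f.silhouette_profile.itertuples()
                )
            lines.append(f"  until {f.cutoff}: n={f.n_records:4d}  k*={f.k}  [{prof}]")
        lines += ["", "Most probable introduction areas (geoprofile peaks)", "-" * 72]
        tbl = self.origins_table()
        lines.append(tbl.to_string(index=False))
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------------

    def plot_silhouette(self, ax=None):
        """Silhouette-vs-k profiles, one line per cutoff."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for f in self.fits:
            if f.silhouette_profile is not None:
                ax.plot(f.silhouette_profile["k"], f.silhouette_profile["mean_silhouette"], marker="o", label=f"until {f.cutoff}")
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("mean silhouette width")
        ax.legend()
        return ax

    def plot_geoprofile(self, cutoff: int, cluster: int = 0, ax=None):
        """Heatmap of one cluster's surface with its observations and peak."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cg = self[cutoff].clusters[cluster]
        gp = cg.geoprofile
        ax.imshow(gp.scores, origin="lower", extent=gp.extent, aspect="auto", cmap="hot")
        ax.scatter(cg.points[:, 0], cg.points[:, 1], s=12, c="cyan", edgecolors="k", linewidths=0.3)
        ax.plot(*cg.origin.peak_lonlat, marker="*", ms=14, c="lime")
        ax.set_title(f"until {cutoff}, cluster {cluster}")
        ax.set_xlabel("lon")
        ax.set_ylabel("lat")
        return ax
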