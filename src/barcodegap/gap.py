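"""Barcoding-gap assessment from pooled intra- and interspecific distances.

Two criteria are implemented.  The min-max criterion declares species
boundaries delineated when the lowest interspecific distance exceeds the
highest intraspecific distance, both on the full pools and after excluding
the largest 5% of intraspecific and the smallest 5% of interspecific values
(the "90% pairwise distances" variant).  The fold criterion requires the
pooled mean interspecific distance to exceed the pooled mean intraspecific
distance at least ten-fold (inclusive boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import SpecimenRecord
from .distances import DistanceMatrix


class GapError(ValueError):
    pass


@dataclass(frozen=True)
class PairPartition:
    """Valid pairwise distances split by species membership of each pair."""

    intra: dict[str, list[float]]  # species -> distances
    inter: dict[tuple[str, str], list[float]]  # sorted species pair -> distances

    @property
    def pooled_intra(self) -> list[float]:
        return [d for pool in self.intra.values() for d in pool]

    @property
    def pooled_inter(self) -> list[float]:
        return [d for pool in self.inter.values() for d in pool]


def partition_distances(
    m: DistanceMatrix,
    records: list[SpecimenRecord] | tuple[SpecimenRecord, ...],
    focal_species: set[str] | None = None,
) -> PairPartition:
    """Pool valid off-diagonal distances into intra/inter groups.

    With ``focal_species`` given, pairs touching any other species are
    dropped (e.g. restricting a study table to the two focal species).
    """
    species = {r.specimen_id: r.species_label for r in records}
    missing = [sid for sid in m.ids if sid not in species]
    if missing:
        raise GapError(f"ids without species label: {missing}")
    if focal_species is not None:
        unknown = focal_species - set(species.values())
        if unknown:
            raise GapError(f"focal species not observed: {sorted(unknown)}")

    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    n = len(m.ids)
    for i in range(n):
        sp_i = species[m.ids[i]]
        for j in range(i + 1, n):
            sp_j = species[m.ids[j]]
            if not m.valid[i, j]:
                continue
            if focal_species is not None and (sp_i not in focal_species or sp_j not in focal_species):
                continue
            d = float(m.values[i, j])
            if sp_i == sp_j:
                intra.setdefault(sp_i, []).append(d)
            else:
                inter.setdefault(tuple(sorted((sp_i, sp_j))), []).append(d)
    return PairPartition(intra=intra, inter=inter)


def _trimmed(pool: list[float], k: int, largest: bool) -> list[float]:
    s = sorted(pool)
    return s[: len(s) - k] if largest else s[k:]


def gap_criterion_minmax(p: PairPartition, trim_fraction: float = 0.05) -> tuple[float, float]:
    """(gap_full, gap_trimmed): min inter minus max intra, full and trimmed.

    Trimming removes floor(trim_fraction * n) of the largest intraspecific
    and floor(trim_fraction * m) of the smallest interspecific values.  A
    positive gap means the min-max criterion delineates the species.
    """
    intra, inter = p.pooled_intra, p.pooled_inter
    if not intra or not inter:
        raise GapError("min-max gap undefined: empty intra or inter pool")
    if not 0 <= trim_fraction < 0.5:
        raise GapError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    gap_full = min(inter) - max(intra)
    k_intra = math.floor(trim_fraction * len(intra))
    k_inter = math.floor(trim_fraction * len(inter))
    gap_trimmed = min(_trimmed(inter, k_inter, largest=False)) - max(
        _trimmed(intra, k_intra, largest=True)
    )
    return gap_full, gap_trimmed


def gap_criterion_fold(p: PairPartition, fold: float = 10.0) -> tuple[float, bool]:
    """(fold_ratio, pass): pooled mean inter / pooled mean intra vs a 10-fold bar.

    A zero mean intraspecific distance yields an infinite ratio (pass).  The
    boundary is inclusive: ratio == fold passes.
    """
    intra, inter = p.pooled_intra, p.pooled_inter
    if not intra or not inter:
        raise GapError("fold ratio undefined: empty intra or inter pool")
    mean_intra = float(np.mean(intra))
    mean_inter = float(np.mean(inter))
    ratio = math.inf if mean_intra == 0.0 else mean_inter / mean_intra
    return ratio, ratio >= fold


def summary_table(p: PairPartition) -> pd.DataFrame:
    """Per-species intraspecific and pooled interspecific min/mean/max (percent).

    Mirrors the usual study-table layout: one row per species for the
    intraspecific pools, one pooled interspecific row; values in percent.
    """
    rows = []
    for sp in sorted(p.intra):
        pool = p.intra[sp]
        rows.append(
            {
                "group": "intraspecific",
                "taxon": sp,
                "n_pairs": len(pool),
                "min_pct": 100 * min(pool),
                "mean_pct": 100 * float(np.mean(pool)),
                "max_pct": 100 * max(pool),
            }
        )
    inter = p.pooled_inter
    if inter:
        rows.append(
            {
                "group": "interspecific",
                "taxon": "pooled",
                "n_pairs": len(inter),
                "min_pct": 100 * min(inter),
                "mean_pct": 100 * float(np.mean(inter)),
                "max_pct": 100 * max(inter),
            }
        )
    df = pd.DataFrame(rows)
    for col in ("min_pct", "mean_pct", "max_pct"):
        df[col] = df[col].round(1)
    return df


@dataclass(frozen=True)
class GapReport:
    """Both gap criteria plus the distance-summary table."""

    max_intra: float
    min_inter: float
    gap_full: float
    gap_trimmed: float
    mean_intra: float
    mean_inter: float
    fold_ratio: float
    tenfold_pass: bool
    summary: pd.DataFrame


def gap_report(p: PairPartition, trim_fraction: float = 0.05) -> GapReport:
    gap_full, gap_trimmed = gap_criterion_minmax(p, trim_fraction)
    fold_ratio, tenfold = gap_criterion_fold(p)
    return GapReport(
        max_intra=max(p.pooled_intra),
        min_inter=min(p.pooled_inter),
        gap_full=gap_full,
        gap_trimmed=gap_trimmed,
        mean_intra=float(np.mean(p.pooled_intra)),
        mean_inter=float(np.mean(p.pooled_inter)),
        fold_ratio=fold_ratio,
        tenfold_pass=tenfold,
        summary=summary_table(p),
    )


def distance_histogram(pool: list[float], bin_width: float) -> pd.DataFrame:
    """Left-closed right-open bins from 0; counts conserve the pool size."""
    if bin_width <= 0:
        raise GapError("bin_width must be positive")
    if not pool:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    idx = np.floor(np.asarray(pool) / bin_width).astype(int)
    counts = np.bincount(idx)
    nz = np.nonzero(counts)[0]
    return pd.DataFrame(
        {
            "bin_start": nz * bin_width,
            "bin_end": (nz + 1) * bin_width,
            "count": counts[nz],
        }
    )


def write_gap_report(report: GapReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("# distance summary (percent)\n")
        report.summary.to_csv(fh, sep="\t", index=False)
        fh.write("\n# gap criteria (percent where applicable)\n")
        fh.write("metric\tvalue\n")
        fh.write(f"max_intra_pct\t{100 * report.max_intra:.2f}\n")
        fh.write(f"min_inter_pct\t{100 * report.min_inter:.2f}\n")
        fh.write(f"gap_full_pct\t{100 * report.gap_full:.2f}\n")
        fh.write(f"gap_trimmed_pct\t{100 * report.gap_trimmed:.2f}\n")
        fh.write(f"mean_intra_pct\t{100 * report.mean_intra:.2f}\n")
        fh.write(f"mean_inter_pct\t{100 * report.mean_inter:.2f}\n")
        fold = "inf" if math.isinf(report.fold_ratio) else f"{report.fold_ratio:.2f}"
        fh.write(f"fold_ratio\t{fold}\n")
        fh.write(f"minmax_pass\t{report.gap_full > 0}\n")
        fh.write(f"tenfold_pass\t{report.tenfold_pass}\n")
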