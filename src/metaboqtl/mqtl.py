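"""mQTL locus definition: region merging, LD and sentinel selection.

Each significant (variant, metabolite) hit seeds a 1 Mb window; starting at
the lowest p-value, overlapping windows for the same metabolite are merged
to a fixed point, and regions whose lead variants are in linkage
disequilibrium (r^2 >= 0.8) are combined again. The sentinel is the most
significant member of the final region.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GenotypeData, MqtlRegion
from .scan import ScanThreshold

__all__ = ["merge_regions", "ld_r2", "combine_ld_leads", "regions_to_frame"]

logger = logging.getLogger(__name__)


def _sentinel(members: pd.DataFrame) -> pd.Series:
    # lowest p; ties by genomic position then allele lexicographic order
    return members.sort_values(["p", "pos", "ref", "alt"], kind="stable").iloc[0]


def merge_regions(
    hits: pd.DataFrame,
    threshold: ScanThreshold | float | None = None,
    window: int = 1_000_000,
) -> list[MqtlRegion]:
    """Merge significant hits into per-metabolite mQTL regions.

    Every hit below the threshold gets the 1-based inclusive interval
    ``[pos - window/2 + 1, pos + window/2]`` (clipped at 1). Hits are
    processed in ascending p; an interval overlapping the growing region is
    absorbed (union hull, members pooled), repeated to a fixed point. The
    default window of 1 Mb means ±500 kb around the variant.
    """
    if threshold is not None:
        cut = threshold.threshold if isinstance(threshold, ScanThreshold) else float(threshold)
        hits = hits[hits["p"] < cut]
    if hits.empty:
        return []

    half = window // 2
    regions: list[MqtlRegion] = []
    for (met, chrom), grp in hits.groupby(["metabolite", "chrom"], sort=True):
        grp = grp.sort_values(["p", "pos", "ref", "alt"], kind="stable")
        open_regions: list[dict] = []
        for _, hit in grp.iterrows():
            start = max(int(hit["pos"]) - half + 1, 1)
            end = int(hit["pos"]) + half
            merged_into = None
            for reg in open_regions:
                if start <= reg["end"] and end >= reg["start"]:
                    reg["start"] = min(reg["start"], start)
                    reg["end"] = max(reg["end"], end)
                    reg["rows"].append(hit)
                    merged_into = reg
                    break
            if merged_into is None:
                open_regions.append({"start": start, "end": end, "rows": [hit]})
        # growing a region can create new overlaps between regions: repeat
        changed = True
        while changed:
            changed = False
            for i in range(len(open_regions)):
                for j in range(i + 1, len(open_regions)):
                    a, b = open_regions[i], open_regions[j]
                    if a["start"] <= b["end"] and b["start"] <= a["end"]:
                        a["start"] = min(a["start"], b["start"])
                        a["end"] = max(a["end"], b["end"])
                        a["rows"].extend(b["rows"])
                        del open_regions[j]
                        changed = True
                        break
                if changed:
                    break
        for reg in open_regions:
            members = pd.DataFrame(reg["rows"]).reset_index(drop=True)
            sent = _sentinel(members)
            regions.append(
                MqtlRegion(
                    metabolite=met,
                    chrom=str(chrom),
                    start=reg["start"],
                    end=reg["end"],
                    members=members,
                    sentinel=str(sent["variant"]),
                    sentinel_p=float(sent["p"]),
                )
            )
    regions.sort(key=lambda r: (r.metabolite, r.chrom, r.start))
    return regions


def ld_r2(genotypes: GenotypeData, v1: str, v2: str) -> float:
    """Composite LD: squared Pearson correlation of dosage vectors.

    Computed over complete-case samples; a monomorphic variant makes the
    correlation undefined, returned as NaN.
    """
    a = genotypes.dosages[v1].to_numpy(float)
    b = genotypes.dosages[v2].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("LD requires at least 2 complete-case samples")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        logger.warning("monomorphic variant in LD computation: r2 undefined")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def combine_ld_leads(
    regions: list[MqtlRegion],
    genotypes: GenotypeData,
    r2_min: float = 0.8,
) -> list[MqtlRegion]:
    """Combine same-metabolite regions whose sentinels are in LD.

    Two regions merge when their sentinels have r^2 >= ``r2_min`` (an
    inclusive bound) and lie on the same chromosome; applied transitively
    to a fixed point. Cross-chromosome LD above the bound can occur by
    chance and is logged but never combined. The combined interval is the
    union hull and the sentinel is the member with the lowest p.
    """
    by_met: dict[str, list[MqtlRegion]] = {}
    for r in regions:
        by_met.setdefault(r.metabolite, []).append(r)

    out: list[MqtlRegion] = []
    for met, regs in by_met.items():
        parent = list(range(len(regs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                if regs[i].sentinel == regs[j].sentinel:
                    r2 = 1.0
                else:
                    r2 = ld_r2(genotypes, regs[i].sentinel, regs[j].sentinel)
                if np.isnan(r2) or r2 < r2_min:
                    continue
                if regs[i].chrom != regs[j].chrom:
                    logger.warning(
                        "sentinels %s/%s in LD (r2=%.2f) across chromosomes: not combined",
                        regs[i].sentinel, regs[j].sentinel, r2,
                    )
                    continue
                parent[find(i)] = find(j)

        groups: dict[int, list[MqtlRegion]] = {}
        for i, r in enumerate(regs):
            groups.setdefault(find(i), []).append(r)
        for members in groups.values():
            if len(members) == 1:
                out.append(members[0])
                continue
            pooled = pd.concat([m.members for m in members], ignore_index=True)
            sent = _sentinel(pooled)
            out.append(
                MqtlRegion(
                    metabolite=met,
                    chrom=members[0].chrom,
                    start=min(m.start for m in members),
                    end=max(m.end for m in members),
                    members=pooled,
                    sentinel=str(sent["variant"]),
                    sentinel_p=float(sent["p"]),
                )
            )
    out.sort(key=lambda r: (r.metabolite, r.chrom, r.start))
    return out


def regions_to_frame(regions: list[MqtlRegion]) -> pd.DataFrame:
    """BED-like summary (half-open start) of mQTL regions."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start - 1,
                "end": r.end,
                "metabolite": r.metabolite,
                "sentinel": r.sentinel,
                "sentinel_p": r.sentinel_p,
                "n_members": len(r.members),
            }
            for r in regions
        ]
    )
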