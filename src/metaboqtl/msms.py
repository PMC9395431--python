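"""MS/MS scan matching, consensus spectra, cosine scoring and networking.

Replicate fragmentation scans of a feature are aggregated into a consensus
spectrum (fragments grouped within a ppm tolerance, inconsistently detected
peaks dropped, the well-known electronic-noise fragment near m/z 173.46
removed). Consensus spectra are compared by a greedy one-to-one cosine on
square-root-weighted intensities, and pairs above a similarity threshold
form the edges of a molecular network.
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np

from .containers import MsmsSpectrum
from .simulate import ELECTRONIC_NOISE_MZ

__all__ = ["match_scans", "consensus_spectrum", "cosine_score", "build_network"]

NOISE_TOL_PPM = 30.0


def match_scans(
    feature,
    scans: list[MsmsSpectrum],
    mz_tol: float = 0.2,
    rt_tol: float = 0.1,
) -> list[MsmsSpectrum]:
    """Select the scans whose precursor matches a feature.

    A scan matches when its precursor m/z is within ``mz_tol`` Da of the
    feature m/z and its retention time within ``rt_tol`` min of the
    feature's apex. ``feature`` is any mapping/record with ``mz`` and
    ``rt`` fields. Returns an empty list when nothing matches.
    """
    fmz = float(feature["mz"] if not hasattr(feature, "mz") else feature.mz)
    frt = float(feature["rt"] if not hasattr(feature, "rt") else feature.rt)
    return [
        s
        for s in scans
        if abs(s.precursor_mz - fmz) <= mz_tol and abs(s.rt - frt) <= rt_tol
    ]


def consensus_spectrum(
    scans: list[MsmsSpectrum],
    frag_ppm: float = 5.0,
    min_scan_fraction: float = 0.5,
    noise_mz: float = ELECTRONIC_NOISE_MZ,
    noise_tol_ppm: float = NOISE_TOL_PPM,
) -> MsmsSpectrum:
    """Aggregate replicate scans into one consensus spectrum.

    Fragments across scans are grouped within ``frag_ppm``; each group's
    consensus m/z is the intensity-weighted mean and its intensity the
    mean over contributing scans. Groups seen in fewer than
    ``min_scan_fraction`` of the scans are dropped as inconsistently
    detected, and any fragment within ``noise_tol_ppm`` of the electronic
    noise m/z (173.46 by default) is removed.
    """
    if not scans:
        raise ValueError("consensus requires at least one scan")
    n_scans = len(scans)

    mz = np.concatenate([s.mz for s in scans])
    inten = np.concatenate([s.intensity for s in scans])
    scan_of = np.concatenate([np.full(len(s), i) for i, s in enumerate(scans)])
    order = np.argsort(mz, kind="stable")
    mz, inten, scan_of = mz[order], inten[order], scan_of[order]

    # chain grouping: a new group starts when the gap to the previous
    # fragment exceeds the ppm tolerance
    group = np.zeros(len(mz), dtype=int)
    gid = 0
    for i in range(1, len(mz)):
        if (mz[i] - mz[i - 1]) / mz[i - 1] * 1e6 > frag_ppm:
            gid += 1
        group[i] = gid

    out_mz, out_int = [], []
    for g in range(gid + 1):
        sel = group == g
        support = len(np.unique(scan_of[sel]))
        if support / n_scans < min_scan_fraction:
            continue
        w = inten[sel]
        cmz = float(np.average(mz[sel], weights=w)) if w.sum() > 0 else float(mz[sel].mean())
        if abs(cmz - noise_mz) / noise_mz * 1e6 <= noise_tol_ppm:
            continue
        # mean across contributing scans (a scan contributing two fragments
        # to one group counts its summed intensity once)
        per_scan = {}
        for s_idx, iv in zip(scan_of[sel], inten[sel]):
            per_scan[s_idx] = per_scan.get(s_idx, 0.0) + iv
        out_mz.append(cmz)
        out_int.append(float(np.mean(list(per_scan.values()))))

    first = scans[0]
    return MsmsSpectrum(
        precursor_mz=float(np.mean([s.precursor_mz for s in scans])),
        rt=float(np.mean([s.rt for s in scans])),
        collision_energy=first.collision_energy,
        mz=np.array(out_mz),
        intensity=np.array(out_int),
        feature_id=first.feature_id,
    )


def cosine_score(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    frag_tol_ppm: float = 10.0,
    sqrt_weight: bool = True,
) -> float:
    """Greedy one-to-one spectral cosine similarity in [0, 1].

    Candidate fragment pairs within ``frag_tol_ppm`` are taken in
    decreasing order of intensity product, each fragment used at most once;
    the score is the matched dot product of (square-root by default)
    intensities over the product of vector norms. Symmetric and invariant
    to global intensity scaling of either spectrum.
    """
    if len(a) == 0 or len(b) == 0:
        warnings.warn("cosine of empty spectrum is 0")
        return 0.0
    wa = np.sqrt(a.intensity) if sqrt_weight else a.intensity.astype(float)
    wb = np.sqrt(b.intensity) if sqrt_weight else b.intensity.astype(float)

    pairs = []
    for i, ma in enumerate(a.mz):
        tol = ma * frag_tol_ppm * 1e-6
        lo = np.searchsorted(b.mz, ma - tol, side="left")
        hi = np.searchsorted(b.mz, ma + tol, side="right")
        for j in range(lo, hi):
            pairs.append((wa[i] * wb[j], i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_a, used_b = set(), set()
    dot = 0.0
    for prod, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += prod
    denom = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    return min(dot / denom, 1.0) if denom > 0 else 0.0


def build_network(
    spectra: list[MsmsSpectrum],
    threshold: float = 0.7,
    frag_tol_ppm: float = 10.0,
    roles: dict[str, str] | None = None,
) -> nx.Graph:
    """All-pairs molecular network with edges above the cosine threshold.

    Nodes are consensus spectra keyed by (feature id, collision energy) —
    spectra at different collision energies stay separate nodes. ``roles``
    optionally annotates nodes (e.g. primary ion vs potential
    adduct/fragment from the clustering stage). Edge attribute ``cosine``
    holds the score; only scores strictly above ``threshold`` are kept.
    """
    g = nx.Graph()
    keys = []
    for idx, sp in enumerate(spectra):
        key = (sp.feature_id or f"spectrum{idx}", str(sp.collision_energy))
        keys.append(key)
        role = (roles or {}).get(sp.feature_id or "", "")
        g.add_node(key, precursor_mz=sp.precursor_mz, rt=sp.rt, role=role)
    for (i, si), (j, sj) in itertools.combinations(enumerate(spectra), 2):
        score = cosine_score(si, sj, frag_tol_ppm=frag_tol_ppm)
        if score > threshold:
            g.add_edge(keys[i], keys[j], cosine=score)
    return g
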