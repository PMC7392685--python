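"""Sequence-level statistics on allele panels.

Implements the standard descriptive and neutrality statistics of a DnaSP-style
analysis on an aligned haplotype panel with sample multiplicities: segregating
sites S, mean pairwise differences k, per-site nucleotide diversity pi,
haplotype diversity Hd, Tajima's D, Fu & Li's D* and F*, and Fu's Fs (exact
Ewens-sampling-formula tail computed in exact rational arithmetic).  Gap
handling is complete deletion: every column containing a gap in any row is
excluded throughout, so pi * L == k holds identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from Bio.Seq import Seq

__all__ = [
    "AlignedPanel",
    "DiversityStats",
    "NeutralityStats",
    "segregating_sites",
    "pairwise_differences",
    "diversity",
    "tajimas_d",
    "fu_li_star_tests",
    "fus_fs",
    "neutrality_stats",
    "translate_and_collapse",
    "distances",
    "mutation_counts",
]

GAP = "-"


@dataclass
class AlignedPanel:
    """Equal-length sequences with per-sequence sample multiplicity.

    Multiplicity m_i is the number of copies of haplotype i in the population
    sample (2 per homozygote, 1 per heterozygous carrier); unit multiplicities
    analyse the distinct alleles themselves.
    """

    locus: str
    names: list[str]
    seqs: list[str]
    multiplicities: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise ValueError("names and seqs length mismatch")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"aligned panel requires equal-length rows, got lengths {sorted(lengths)}")
        if self.multiplicities is None:
            self.multiplicities = [1] * len(self.seqs)
        self.multiplicities = [int(m) for m in self.multiplicities]
        if len(self.multiplicities) != len(self.seqs):
            raise ValueError("multiplicities length mismatch")
        if any(m < 1 for m in self.multiplicities):
            raise ValueError("multiplicities must be >= 1")

    @property
    def n_rows(self) -> int:
        return len(self.seqs)

    @property
    def n(self) -> int:
        """Total sampled sequence copies."""
        return int(sum(self.multiplicities))

    @property
    def alignment_length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def gap_column_mask(self) -> np.ndarray:
        """True for columns containing a gap in any row (complete deletion)."""
        if not self.seqs:
            return np.zeros(0, dtype=bool)
        arr = np.array([list(s) for s in self.seqs])
        return (arr == GAP).any(axis=0)

    def columns(self) -> np.ndarray:
        """Character matrix restricted to gap-free columns."""
        arr = np.array([list(s) for s in self.seqs])
        if arr.size == 0:
            return arr
        return arr[:, ~self.gap_column_mask()]

    @property
    def L(self) -> int:
        """Number of sites used (gap-free columns)."""
        return int(self.columns().shape[1]) if self.seqs else 0

    def with_multiplicities(self, mult: Sequence[int]) -> "AlignedPanel":
        return AlignedPanel(self.locus, list(self.names), list(self.seqs), list(mult))

    def unique(self) -> "AlignedPanel":
        return AlignedPanel(self.locus, list(self.names), list(self.seqs), None)


@dataclass
class DiversityStats:
    S: int
    k: float
    pi: float
    hd: float
    n: int
    L: int


@dataclass
class NeutralityStats:
    tajima_d: float
    fu_li_dstar: float
    fu_li_fstar: float
    fus_fs: float
    eta: int
    eta_s: int
    theta_w: float
    fs_overflow: bool = False
    bands: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# descriptive statistics


def segregating_sites(panel: AlignedPanel) -> tuple[int, list[int]]:
    """Count gap-free alignment columns with >= 2 distinct states (positions
    returned in 0-based coordinates of the full alignment).  Invariant to
    multiplicities."""
    mask = panel.gap_column_mask()
    arr = np.array([list(s) for s in panel.seqs])
    sites = []
    for j in range(arr.shape[1] if arr.size else 0):
        if mask[j]:
            continue
        if len(set(arr[:, j])) >= 2:
            sites.append(j)
    return len(sites), sites


def mutation_counts(panel: AlignedPanel) -> tuple[int, int]:
    """(eta, eta_s): total mutations and singleton mutations.

    A column with c distinct states contributes c - 1 mutations; a state whose
    total copy count (multiplicity-weighted) is exactly 1 is a singleton."""
    mask = panel.gap_column_mask()
    arr = np.array([list(s) for s in panel.seqs])
    mult = np.asarray(panel.multiplicities)
    eta = 0
    eta_s = 0
    for j in range(arr.shape[1] if arr.size else 0):
        if mask[j]:
            continue
        states, idx = np.unique(arr[:, j], return_inverse=True)
        if len(states) < 2:
            continue
        eta += len(states) - 1
        copies = np.bincount(idx, weights=mult)
        eta_s += int((copies == 1).sum())
    return eta, eta_s


def _pair_matrix(panel: AlignedPanel) -> np.ndarray:
    cols = panel.columns()
    nr = panel.n_rows
    d = np.zeros((nr, nr))
    for i, j in combinations(range(nr), 2):
        d[i, j] = d[j, i] = int((cols[i] != cols[j]).sum())
    return d


def pairwise_differences(panel: AlignedPanel) -> tuple[float, np.ndarray]:
    """Multiplicity-weighted mean number of pairwise nucleotide differences k
    and the per-haplotype-pair difference matrix (gap columns excluded)."""
    if panel.n < 2:
        return float("nan"), np.zeros((panel.n_rows, panel.n_rows))
    d = _pair_matrix(panel)
    m = np.asarray(panel.multiplicities, dtype=float)
    total = 0.0
    for i, j in combinations(range(panel.n_rows), 2):
        total += m[i] * m[j] * d[i, j]
    npairs = panel.n * (panel.n - 1) / 2
    return total / npairs, d


def diversity(panel: AlignedPanel) -> DiversityStats:
    """pi = k / L and Hd = n/(n-1) (1 - sum p_i^2) over haplotype frequencies."""
    if panel.n < 2:
        raise ValueError("diversity requires n >= 2 sampled sequences")
    S, _ = segregating_sites(panel)
    k, _ = pairwise_differences(panel)
    L = panel.L
    pi = k / L if L else float("nan")
    # identical rows are pooled into haplotype classes first
    klass: dict[str, int] = {}
    for s, m in zip(panel.seqs, panel.multiplicities):
        klass[s] = klass.get(s, 0) + m
    n = panel.n
    freqs = np.array([c / n for c in klass.values()])
    hd = n / (n - 1) * (1.0 - float((freqs**2).sum()))
    return DiversityStats(S=S, k=k, pi=pi, hd=hd, n=n, L=L)


# ---------------------------------------------------------------------------
# neutrality tests


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def tajimas_d(panel: AlignedPanel) -> float:
    """Tajima's D from S and k with the standard variance constants."""
    n = panel.n
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    S, _ = segregating_sites(panel)
    if S == 0:
        return float("nan")
    k, _ = pairwise_differences(panel)
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def _fu_li_constants(n: int) -> dict[str, float]:
    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n  # a_{n+1}
    if n == 2:
        cn = 1.0
    else:
        cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    if n == 2:
        dn = 2.0
    else:
        dn = cn + (n - 2) / (n - 1) ** 2 + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    # D* (corrected form)
    vd = ((n / (n - 1.0)) ** 2 * bn + an**2 * dn - 2 * (n * an * (an + 1)) / (n - 1.0) ** 2) / (an**2 + bn)
    ud = (n / (n - 1.0)) * (an - n / (n - 1.0)) - vd
    # F* (corrected form)
    vf = (dn + 2 * (n**2 + n + 3.0) / (9 * n * (n - 1.0)) - (2.0 / (n - 1)) * (4 * bn - 6 + 8.0 / n)) / (
        an**2 + bn
    )
    uf = (
        n / (n - 1.0)
        + (n + 1.0) / (3 * (n - 1.0))
        - 4.0 / (n * (n - 1.0))
        + 2 * (n + 1.0) / (n - 1.0) ** 2 * (an1 - 2.0 * n / (n + 1))
    ) / an - vf
    return {"an": an, "bn": bn, "cn": cn, "dn": dn, "ud": ud, "vd": vd, "uf": uf, "vf": vf}


def fu_li_star_tests(panel: AlignedPanel) -> tuple[float, float]:
    """Fu & Li's D* and F* (no-outgroup tests) using total mutations eta and
    singleton mutations eta_s with the corrected variance constants."""
    n = panel.n
    if n < 4:
        raise ValueError("Fu & Li tests require n >= 4")
    eta, eta_s = mutation_counts(panel)
    if eta == 0:
        return float("nan"), float("nan")
    k, _ = pairwise_differences(panel)
    c = _fu_li_constants(n)
    dstar = ((n / (n - 1.0)) * eta - c["an"] * eta_s) / math.sqrt(c["ud"] * eta + c["vd"] * eta**2)
    fstar = (k - ((n - 1.0) / n) * eta_s) / math.sqrt(c["uf"] * eta + c["vf"] * eta**2)
    return dstar, fstar


def _stirling_row(n: int) -> list[int]:
    """Unsigned Stirling numbers of the first kind c(n, k) for k = 0..n."""
    row = [1]
    for m in range(n):
        new = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    return row


def ewens_k_tail(n: int, k_obs: int, theta: float) -> Fraction:
    """P(K >= k_obs) for the number of distinct haplotypes K in a sample of n
    under the Ewens sampling formula with parameter theta, computed exactly:
    P(K = k) = c(n, k) theta^k / (theta)_n with unsigned Stirling numbers."""
    th = Fraction(theta)
    row = _stirling_row(n)
    rising = Fraction(1)
    for i in range(n):
        rising *= th + i
    num = Fraction(0)
    power = th**k_obs
    for k in range(k_obs, n + 1):
        num += row[k] * power
        power *= th
    return num / rising


def fus_fs(panel: AlignedPanel) -> tuple[float, bool]:
    """Fu's Fs = ln(S'/(1-S')), S' = P(K >= K_obs | theta = k).

    Returns (value, overflow) where overflow flags S' at the 0/1 boundary
    (signed infinity reported)."""
    n = panel.n
    if n < 2:
        raise ValueError("Fu's Fs requires n >= 2")
    k, _ = pairwise_differences(panel)
    if not (k > 0):
        raise ValueError("Fu's Fs requires k > 0")
    klass: dict[str, int] = {}
    for s in panel.seqs:
        klass[s] = klass.get(s, 0) + 1
    # K_obs counts distinct haplotypes present in the sample (multiplicities
    # do not add new haplotypes)
    k_obs = len(klass)
    sp = ewens_k_tail(n, k_obs, k)
    if sp <= 0:
        return float("-inf"), True
    if sp >= 1:
        return float("inf"), True
    ratio = sp / (1 - sp)
    # math.log on the big-integer numerator/denominator keeps full precision
    # even when S' is within 1e-300 of the boundary
    return math.log(ratio.numerator) - math.log(ratio.denominator), False


# Approximate two-sided critical values for the 0.05 and 0.10 levels of the
# no-outgroup Fu & Li statistics (interpolated from the published tables;
# indicative bands only, not exact p-values).
_FU_LI_CRIT = {"0.05": (-2.3, 1.6), "0.10": (-1.9, 1.42)}
_TAJIMA_CRIT = {"0.05": (-1.8, 1.96), "0.10": (-1.55, 1.62)}


def _band(value: float, crit: dict[str, tuple[float, float]]) -> str:
    if math.isnan(value):
        return ""
    lo5, hi5 = crit["0.05"]
    lo10, hi10 = crit["0.10"]
    if value < lo5 or value > hi5:
        return "*"  # p < 0.05
    if value < lo10 or value > hi10:
        return "^"  # 0.05 < p < 0.10
    return "ns"


def neutrality_stats(panel: AlignedPanel) -> NeutralityStats:
    """The full neutrality bundle; statistics undefined at S = 0 come back NaN."""
    n = panel.n
    S, _ = segregating_sites(panel)
    eta, eta_s = mutation_counts(panel)
    a1 = _harmonic(n) if n > 1 else float("nan")
    theta_w = S / a1 if (n > 1 and S) else 0.0
    if S == 0:
        return NeutralityStats(
            tajima_d=float("nan"), fu_li_dstar=float("nan"), fu_li_fstar=float("nan"),
            fus_fs=float("nan"), eta=0, eta_s=0, theta_w=0.0,
        )
    d = tajimas_d(panel) if n >= 4 else float("nan")
    dstar, fstar = fu_li_star_tests(panel) if n >= 4 else (float("nan"), float("nan"))
    k, _ = pairwise_differences(panel)
    if k > 0:
        fs, overflow = fus_fs(panel)
    else:
        fs, overflow = float("nan"), False
    bands = {
        "tajima_d": _band(d, _TAJIMA_CRIT),
        "fu_li_dstar": _band(dstar, _FU_LI_CRIT),
        "fu_li_fstar": _band(fstar, _FU_LI_CRIT),
    }
    return NeutralityStats(
        tajima_d=d, fu_li_dstar=dstar, fu_li_fstar=fstar, fus_fs=fs,
        eta=eta, eta_s=eta_s, theta_w=theta_w, fs_overflow=overflow, bands=bands,
    )


# ---------------------------------------------------------------------------
# translation and distances


def translate_and_collapse(
    panel: AlignedPanel, frame_offset: int = 0
) -> tuple[AlignedPanel, dict[str, list[str]]]:
    """Translate each row with the standard code and merge identical proteins.

    Gaps must occur in whole-codon blocks (in-frame indels; translated as a
    one-character gap).  Internal stop codons are flagged with a warning but
    the sequence is retained (amplicons are exon fragments).  Returns the
    protein panel (multiplicities summed over merged rows) and a collapse map
    protein-panel-name -> contributing nucleotide allele names.
    """
    proteins: list[str] = []
    for name, s in zip(panel.names, panel.seqs):
        nt = s[frame_offset:]
        nt = nt[: len(nt) - len(nt) % 3]
        aa_chars = []
        for i in range(0, len(nt), 3):
            codon = nt[i : i + 3]
            if GAP in codon:
                if codon != GAP * 3:
                    raise ValueError(f"{name}: gap not in a whole-codon block at codon {i // 3}")
                aa_chars.append(GAP)
            else:
                aa_chars.append(str(Seq(codon).translate()))
        aa = "".join(aa_chars)
        if "*" in aa[:-1] or aa.endswith("*"):
            warnings.warn(f"internal stop codon in translation of {name}", stacklevel=2)
        proteins.append(aa)

    merged: dict[str, list[int]] = {}
    for i, p in enumerate(proteins):
        merged.setdefault(p, []).append(i)
    names, seqs, mult = [], [], []
    collapse: dict[str, list[str]] = {}
    for p, idxs in merged.items():
        rep = panel.names[idxs[0]]
        names.append(rep)
        seqs.append(p)
        mult.append(sum(panel.multiplicities[i] for i in idxs))
        collapse[rep] = [panel.names[i] for i in idxs]
    return AlignedPanel(panel.locus + "_protein", names, seqs, mult), collapse


def distances(panel: AlignedPanel, kind: str = "nucleotide-p") -> dict:
    """Pairwise p-distances (differences / valid sites) or Poisson-corrected
    amino-acid distances d = -ln(1 - p).  Pairwise deletion of gap sites.
    Returns the matrix plus mean / min / max over unordered pairs."""
    if kind not in ("nucleotide-p", "poisson-aa"):
        raise ValueError(f"unknown distance kind {kind!r}")
    nr = panel.n_rows
    arr = np.array([list(s) for s in panel.seqs])
    mat = np.zeros((nr, nr))
    vals = []
    for i, j in combinations(range(nr), 2):
        valid = (arr[i] != GAP) & (arr[j] != GAP)
        nv = int(valid.sum())
        if nv == 0:
            p = float("nan")
        else:
            p = float((arr[i][valid] != arr[j][valid]).sum()) / nv
        if kind == "poisson-aa":
            d = float("inf") if p >= 1.0 else -math.log(1.0 - p)
        else:
            d = p
        mat[i, j] = mat[j, i] = d
        vals.append(d)
    vals_arr = np.array(vals) if vals else np.array([float("nan")])
    return {
        "matrix": mat,
        "mean": float(np.nanmean(vals_arr)),
        "min": float(np.nanmin(vals_arr)),
        "max": float(np.nanmax(vals_arr)),
        "kind": kind,
    }
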