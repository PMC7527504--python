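"""Neutrality tests: Tajima's D, Fu & Li's D*/F*, McDonald–Kreitman.

Tajima's D contrasts the pairwise-diversity estimator of θ with the
segregating-site estimator; Fu & Li's starred statistics contrast
singleton mutations with the totals and need no outgroup; the
McDonald–Kreitman (MK) test contrasts fixed interspecific differences
with intraspecific polymorphism at synonymous vs non-synonymous
positions.

Partitioned Tajima statistics (``D_S``, ``D_A``) plug class-specific
mutation counts and class-specific mean pairwise differences into the
standard formula — the construction implied by reporting one D per site
class from a single data set.

Undefined statistics (no variation in the relevant class) are reported
as ``None``, never as 0.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Literal

from scipy import stats

from .alignment import Alignment, CodonAlignment
from .diversity import (
    classify_mutations,
    largest_remainder_round,
    mean_pairwise_differences,
    ng_codon_differences,
    site_spectrum,
    _usable_codon,
)

__all__ = [
    "TajimaResult",
    "FuLiResult",
    "MKTable",
    "tajima_constants",
    "tajima_D",
    "tajima_D_partitioned",
    "fu_li_no_outgroup",
    "mk_test",
    "neutrality_table",
]

SiteClass = Literal["all", "synonymous", "nonsynonymous"]


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TajimaResult:
    n: int
    S: int
    k_hat: float  # mean pairwise differences, absolute
    D: float | None
    site_class: SiteClass = "all"


def tajima_constants(n: int) -> dict[str, float]:
    """The Tajima (1989) variance constants a1..e2 for sample size n."""
    if n < 2:
        raise ValueError("n >= 2 required")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _tajima_from_counts(n: int, S: int, k_hat: float,
                        site_class: SiteClass = "all") -> TajimaResult:
    if S <= 0:
        return TajimaResult(n=n, S=S, k_hat=k_hat, D=None, site_class=site_class)
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return TajimaResult(n=n, S=S, k_hat=k_hat, D=None, site_class=site_class)
    D = (k_hat - S / c["a1"]) / math.sqrt(var)
    return TajimaResult(n=n, S=S, k_hat=k_hat, D=D, site_class=site_class)


def tajima_D(aln: Alignment) -> TajimaResult:
    """Tajima's D over all sites of a gap-stripped alignment."""
    spec = site_spectrum(aln)
    k_hat = mean_pairwise_differences(aln)
    return _tajima_from_counts(aln.n, spec.S, k_hat)


def tajima_D_partitioned(
    codon_aln: CodonAlignment,
) -> tuple[TajimaResult, TajimaResult]:
    """Tajima's D restricted to synonymous and to non-synonymous changes.

    Returns ``(D_S result, D_A result)``.  Class mutation counts come
    from pathway classification of each variable codon column (rounded by
    largest remainder); class mean pairwise differences are the mean over
    sequence pairs of the summed pathway-averaged synonymous
    (respectively non-synonymous) per-codon differences.
    """
    syn_f, nonsyn_f = classify_mutations(codon_aln)
    s_syn, s_nonsyn = largest_remainder_round([syn_f, nonsyn_f])
    codons = [codon_aln.codons(i) for i in range(codon_aln.n)]
    k_syn = k_nonsyn = 0.0
    npairs = 0
    for i, j in itertools.combinations(range(codon_aln.n), 2):
        for ca, cb in zip(codons[i], codons[j]):
            if _usable_codon(ca) and _usable_codon(cb):
                nd, ns = ng_codon_differences(ca, cb)
                k_syn += ns
                k_nonsyn += nd
        npairs += 1
    k_syn /= npairs
    k_nonsyn /= npairs
    return (
        _tajima_from_counts(codon_aln.n, s_syn, k_syn, "synonymous"),
        _tajima_from_counts(codon_aln.n, s_nonsyn, k_nonsyn, "nonsynonymous"),
    )


# ---------------------------------------------------------------------------
# Fu & Li's D* and F*
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FuLiResult:
    n: int
    eta: int       # total mutations
    eta_s: int     # singleton mutations (state carried by exactly one sequence)
    D_star: float | None
    F_star: float | None


def _singleton_mutations(aln: Alignment) -> int:
    """Mutations carried by exactly one sequence, summed over columns."""
    total = 0
    for col in aln.columns():
        counts: dict[str, int] = {}
        for c in col:
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        k = len(counts)
        if k < 2:
            continue
        ones = sum(1 for v in counts.values() if v == 1)
        total += min(ones, k - 1)
    return total


def fu_li_no_outgroup(aln: Alignment) -> FuLiResult:
    """Fu & Li's starred statistics D* and F* (no outgroup required).

    Uses the total mutation count η and the singleton count η_s with the
    corrected variance coefficients of Simonsen, Churchill & Aquadro
    (1995), as adopted by the common reference implementations.
    """
    if aln.n < 3:
        raise ValueError("Fu & Li's D*/F* require n >= 3")
    n = aln.n
    spec = site_spectrum(aln)
    eta = spec.eta
    eta_s = _singleton_mutations(aln)
    if eta == 0:
        return FuLiResult(n=n, eta=0, eta_s=0, D_star=None, F_star=None)

    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n  # a_{n+1}

    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (cn + (n - 2) / (n - 1) ** 2
          + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n))

    v_d = ((n / (n - 1.0)) ** 2 * bn + an**2 * dn
           - 2.0 * (n * an * (an + 1.0)) / (n - 1.0) ** 2) / (an**2 + bn)
    u_d = (n / (n - 1.0)) * (an - n / (n - 1.0)) - v_d
    num_d = (n / (n - 1.0)) * eta - an * eta_s
    var_d = u_d * eta + v_d * eta**2
    D_star = num_d / math.sqrt(var_d) if var_d > 0 else None

    k_hat = mean_pairwise_differences(aln)
    v_f = ((2.0 * n**3 + 110.0 * n**2 - 255.0 * n + 153.0) / (9.0 * n**2 * (n - 1))
           + 2.0 * (n - 1) * an / n**2 - 8.0 * bn / n) / (an**2 + bn)
    u_f = ((4.0 * n**2 + 19.0 * n + 3.0 - 12.0 * (n + 1.0) * an1)
           / (3.0 * n * (n - 1.0))) / an - v_f
    num_f = k_hat - (n - 1.0) / n * eta_s
    var_f = u_f * eta + v_f * eta**2
    F_star = num_f / math.sqrt(var_f) if var_f > 0 else None

    return FuLiResult(n=n, eta=eta, eta_s=eta_s, D_star=D_star, F_star=F_star)


# ---------------------------------------------------------------------------
# McDonald–Kreitman test
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MKTable:
    """The MK 2×2 table: fixed vs polymorphic × synonymous vs non-synonymous."""

    f_S: int
    f_A: int
    P_S: int
    P_A: int
    p_value: float | None = None

    @property
    def ratio_fixed(self) -> float | None:
        return self.f_A / self.f_S if self.f_S > 0 else None

    @property
    def ratio_poly(self) -> float | None:
        return self.P_A / self.P_S if self.P_S > 0 else None

    @property
    def neutrality_index(self) -> float | None:
        rf, rp = self.ratio_fixed, self.ratio_poly
        if rf is None or rp is None or rf == 0:
            return None
        return rp / rf


def _consensus_codon(codons: list[str]) -> str | None:
    usable = [c for c in codons if _usable_codon(c)]
    if not usable:
        return None
    counts: dict[str, int] = {}
    for c in usable:
        counts[c] = counts.get(c, 0) + 1
    return max(counts, key=lambda c: (counts[c], c))


def mk_test(
    codon_aln: CodonAlignment,
    outgroup: Alignment,
    method: Literal["fisher", "g"] = "fisher",
) -> MKTable:
    """McDonald–Kreitman test of a focal sample against an outgroup.

    Per codon column: if the focal sample is variable, its mutations are
    counted as polymorphic (regardless of the outgroup state — the
    standard MK convention); if the focal sample is monomorphic and
    differs from the outgroup consensus codon, the differences are
    counted as fixed.  Mutations are typed synonymous/non-synonymous via
    pathway averaging, and the fractional totals rounded by largest
    remainder within each row of the table.  Significance is a two-sided
    Fisher exact test on the 2×2 by default (``method="g"`` uses the
    likelihood-ratio G-test).
    """
    if outgroup.n < 1:
        raise ValueError("MK test requires at least one outgroup sequence")
    if outgroup.length != codon_aln.alignment.length:
        raise ValueError("outgroup must be aligned to the same columns")
    out_codon = CodonAlignment(outgroup, frame_offset=codon_aln.frame_offset,
                               allow_stops=True)
    fixed_s = fixed_a = 0.0
    poly_s, poly_a = classify_mutations(codon_aln)
    for k in range(codon_aln.n_codons):
        focal = [c for c in codon_aln.codon_column(k) if _usable_codon(c)]
        if len(set(focal)) != 1:
            continue  # polymorphic (already counted) or unusable
        ref = focal[0]
        cons = _consensus_codon(out_codon.codon_column(k))
        if cons is None or cons == ref:
            continue
        nd, ns = ng_codon_differences(ref, cons)
        fixed_a += nd
        fixed_s += ns
    f_s, f_a = largest_remainder_round([fixed_s, fixed_a])
    p_s, p_a = largest_remainder_round([poly_s, poly_a])
    table = [[f_s, f_a], [p_s, p_a]]
    if min(f_s + f_a, p_s + p_a) == 0 or min(f_s + p_s, f_a + p_a) == 0:
        p_value = None
    elif method == "fisher":
        p_value = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        res = stats.chi2_contingency(table, correction=False, lambda_="log-likelihood")
        p_value = float(res[1])
    return MKTable(f_S=f_s, f_A=f_a, P_S=p_s, P_A=p_a, p_value=p_value)


# ---------------------------------------------------------------------------
# Report table
# ---------------------------------------------------------------------------

_COLUMNS = ["Name", "fS", "fA", "PS", "PA", "fA/fS", "PA/PS",
            "D_T", "D_S", "D_A", "D*", "F*", "MK_P"]


def _fmt(x: float | None, nd: int = 2) -> str:
    return "NA" if x is None else f"{x:.{nd}f}"


def neutrality_table(rows: list[dict]) -> str:
    """Render per-class neutrality results (dicts of the column values) as TSV.

    Each row dict may contain ``name``, an ``mk`` :class:`MKTable` (or
    ``None``), ``d_t``/``d_s``/``d_a`` :class:`TajimaResult` and ``fu_li``
    :class:`FuLiResult`.  D statistics are printed to 2 dp, ratios to 2 dp.
    """
    lines = ["\t".join(_COLUMNS)]
    for row in rows:
        mk: MKTable | None = row.get("mk")
        d_t: TajimaResult | None = row.get("d_t")
        d_s: TajimaResult | None = row.get("d_s")
        d_a: TajimaResult | None = row.get("d_a")
        fl: FuLiResult | None = row.get("fu_li")
        cells = [row.get("name", "sample")]
        if mk is None:
            cells += ["NA"] * 4 + ["NA", "NA"]
        else:
            cells += [str(mk.f_S), str(mk.f_A), str(mk.P_S), str(mk.P_A),
                      _fmt(mk.ratio_fixed), _fmt(mk.ratio_poly)]
        cells += [_fmt(d_t.D if d_t else None), _fmt(d_s.D if d_s else None),
                  _fmt(d_a.D if d_a else None),
                  _fmt(fl.D_star if fl else None), _fmt(fl.F_star if fl else None),
                  _fmt(mk.p_value, 4) if mk else "NA"]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
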