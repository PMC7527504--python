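"""SSR locus diversity and linkage-disequilibrium scanning.

Works on diploid, unphased, multiallelic genotype tables (individuals ×
loci, two allele codes per locus).  Per-locus diversity statistics:

* ``Ao`` — observed allele count;
* ``Ho`` — observed heterozygote fraction;
* ``He`` — expected heterozygosity, Nei's unbiased estimator
  ``(2n/(2n-1)) * (1 - Σ p_i²)`` by default (plain ``1 - Σ p_i²`` by flag);
* ``PD`` — power of discrimination, ``1 - Σ g_j²`` over observed
  genotype frequencies.

Linkage disequilibrium between allele *a* at one locus and allele *b* at
another uses the composite (Burrows/Weir) measure appropriate for
unphased data: with per-individual allele dosages ``x, y ∈ {0,1,2}``,
``r_ab`` is the Pearson correlation of the dosages (the composite
disequilibrium divided by the Hardy–Weinberg-departure-corrected
variances) and ``r²_ab`` its square.  Significance defaults to a seeded
permutation test of individuals' genotypes at one locus; the asymptotic
chi-square (``n·r²`` vs 1 df) is available by flag.  Rare alleles
(sample frequency strictly below 5% by default) are removed before LD
analysis.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "LocusDiversity",
    "LDResult",
    "read_genotypes",
    "locus_diversity",
    "diversity_rows",
    "rare_allele_filter",
    "ld_scan",
    "export_p_matrix",
    "ssr_table",
]


@dataclasses.dataclass(frozen=True)
class GenotypeTable:
    """Diploid unphased genotype calls.

    ``calls`` maps ``(individual, locus)`` to an unordered allele pair
    (stored as a sorted tuple of strings) or ``None`` for missing.
    ``positions`` optionally maps locus -> map position in cM.
    """

    individuals: tuple[str, ...]
    loci: tuple[str, ...]
    calls: dict[tuple[str, str], tuple[str, str] | None]
    positions: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.individuals) < 2:
            raise ValueError("genotype table requires at least 2 individuals")
        if not self.loci:
            raise ValueError("genotype table requires at least 1 locus")

    def genotypes_at(self, locus: str) -> list[tuple[str, str]]:
        """Non-missing genotype calls at a locus (individual order)."""
        if locus not in self.loci:
            raise KeyError(locus)
        return [g for ind in self.individuals
                if (g := self.calls[(ind, locus)]) is not None]

    def alleles_at(self, locus: str) -> list[str]:
        return [a for g in self.genotypes_at(locus) for a in g]

    def allele_freqs(self, locus: str) -> dict[str, float]:
        alleles = self.alleles_at(locus)
        if not alleles:
            raise ValueError(f"locus {locus!r} has no genotyped individuals")
        n = len(alleles)
        out: dict[str, float] = {}
        for a in alleles:
            out[a] = out.get(a, 0) + 1
        return {a: c / n for a, c in sorted(out.items())}

    def dosage_matrix(self, locus: str) -> pd.DataFrame:
        """Individuals × alleles dosage (0/1/2) matrix; missing rows are NaN."""
        alleles = sorted(set(self.alleles_at(locus)))
        data = np.full((len(self.individuals), len(alleles)), np.nan)
        for i, ind in enumerate(self.individuals):
            g = self.calls[(ind, locus)]
            if g is None:
                continue
            data[i, :] = 0.0
            for a in g:
                data[i, alleles.index(a)] += 1.0
        return pd.DataFrame(data, index=list(self.individuals), columns=alleles)


def read_genotypes(
    path: str | Path,
    missing: str = "NA",
    sep: str = "\t",
    positions: dict[str, float] | None = None,
) -> GenotypeTable:
    """Read a delimited genotype file.

    Layout: header row with an individual-id column followed by two
    columns per locus (``locus`` and ``locus`` repeated, or ``locus.1``/
    ``locus.2`` — only the first label of each pair is used); one row per
    individual; ``missing`` marks an untyped allele (either allele
    missing makes the whole call missing).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 3 or (df.shape[1] - 1) % 2 != 0:
        raise ValueError(
            "expected an id column plus two columns per locus, "
            f"got {df.shape[1]} columns"
        )
    individuals = tuple(df.iloc[:, 0])
    raw_loci = list(df.columns[1::2])
    loci = tuple(l.split(".")[0] if l.split(".")[-1].isdigit() else l
                 for l in raw_loci)
    calls: dict[tuple[str, str], tuple[str, str] | None] = {}
    for row_i, ind in enumerate(individuals):
        for k, locus in enumerate(loci):
            a1 = df.iloc[row_i, 1 + 2 * k].strip()
            a2 = df.iloc[row_i, 2 + 2 * k].strip()
            if not a1 or not a2:
                raise ValueError(
                    f"unparseable genotype at row {row_i + 2}, locus {locus!r}"
                )
            if a1 == missing or a2 == missing:
                calls[(ind, locus)] = None
            else:
                calls[(ind, locus)] = tuple(sorted((a1, a2)))
    return GenotypeTable(individuals=individuals, loci=loci, calls=calls,
                         positions=positions or {})


def write_genotypes(gt: GenotypeTable, path: str | Path, missing: str = "NA",
                    sep: str = "\t") -> None:
    with Path(path).open("w") as fh:
        header = ["id"]
        for locus in gt.loci:
            header += [locus, locus]
        fh.write(sep.join(header) + "\n")
        for ind in gt.individuals:
            cells = [ind]
            for locus in gt.loci:
                g = gt.calls[(ind, locus)]
                cells += list(g) if g is not None else [missing, missing]
            fh.write(sep.join(cells) + "\n")


# ---------------------------------------------------------------------------
# Locus diversity
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LocusDiversity:
    locus: str
    Ao: int
    Ho: float
    He: float
    PD: float


def locus_diversity(gt: GenotypeTable, locus: str,
                    unbiased: bool = True) -> LocusDiversity:
    """Ao/Ho/He/PD for one locus (error if every call is missing)."""
    genos = gt.genotypes_at(locus)
    if not genos:
        raise ValueError(f"locus {locus!r} has no genotyped individuals")
    n = len(genos)
    ho = sum(1 for a, b in genos if a != b) / n
    freqs = gt.allele_freqs(locus)
    he = 1.0 - sum(p**2 for p in freqs.values())
    if unbiased:
        he *= (2 * n) / (2 * n - 1)
    gcounts: dict[tuple[str, str], int] = {}
    for g in genos:
        gcounts[g] = gcounts.get(g, 0) + 1
    pd_ = 1.0 - sum((c / n) ** 2 for c in gcounts.values())
    return LocusDiversity(locus=locus, Ao=len(freqs), Ho=ho, He=he, PD=pd_)


def diversity_rows(gt: GenotypeTable, unbiased: bool = True) -> list[LocusDiversity]:
    return [locus_diversity(gt, loc, unbiased=unbiased) for loc in gt.loci]


def ssr_table(rows: list[LocusDiversity],
              positions: dict[str, float] | None = None) -> str:
    """Per-locus diversity TSV with an Average row (2 dp, Ao mean 1 dp)."""
    positions = positions or {}
    lines = ["Locus\tcM\tAo\tHo\tHe\tPD"]
    for r in rows:
        cm = positions.get(r.locus)
        lines.append("\t".join([
            r.locus, "NA" if cm is None else f"{cm:.2f}", str(r.Ao),
            f"{r.Ho:.2f}", f"{r.He:.2f}", f"{r.PD:.2f}",
        ]))
    k = len(rows)
    lines.append("\t".join([
        "Average", "NA", f"{sum(r.Ao for r in rows) / k:.1f}",
        f"{sum(r.Ho for r in rows) / k:.2f}", f"{sum(r.He for r in rows) / k:.2f}",
        f"{sum(r.PD for r in rows) / k:.2f}",
    ]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Rare-allele filtering
# ---------------------------------------------------------------------------

def rare_allele_filter(gt: GenotypeTable, min_freq: float = 0.05) -> GenotypeTable:
    """Set calls carrying an allele with frequency < ``min_freq`` to missing.

    The inequality is strict (an allele at exactly the threshold is
    retained).  A single pass over the input frequencies is made; filtering
    is not re-applied to the reduced data.  Loci left monomorphic get a
    logged warning and are skipped downstream by :func:`ld_scan`.
    """
    calls = dict(gt.calls)
    for locus in gt.loci:
        freqs = gt.allele_freqs(locus)
        rare = {a for a, p in freqs.items() if p < min_freq}
        if not rare:
            continue
        for ind in gt.individuals:
            g = calls[(ind, locus)]
            if g is not None and (g[0] in rare or g[1] in rare):
                calls[(ind, locus)] = None
        kept = {a for g in (calls[(ind, locus)] for ind in gt.individuals)
                if g is not None for a in g}
        if len(kept) < 2:
            logger.warning(
                "locus %s left monomorphic after rare-allele filtering; "
                "it will be excluded from LD", locus,
            )
    return GenotypeTable(individuals=gt.individuals, loci=gt.loci, calls=calls,
                         positions=gt.positions)


# ---------------------------------------------------------------------------
# LD scan
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LDResult:
    """Allele-level and locus-level LD matrices plus summaries.

    ``allele_r2[pair]`` / ``allele_p[pair]`` are DataFrames indexed by
    alleles of the first locus × alleles of the second; ``locus_r2`` /
    ``locus_p`` are locus × locus DataFrames (NaN where not evaluable).
    ``pct_significant_locus_pairs`` and ``pct_significant_blocks`` are
    percentages at the scan's ``alpha``.
    """

    loci: tuple[str, ...]
    allele_r2: dict[tuple[str, str], pd.DataFrame]
    allele_p: dict[tuple[str, str], pd.DataFrame]
    locus_r2: pd.DataFrame
    locus_p: pd.DataFrame
    alpha: float
    pct_significant_locus_pairs: float
    pct_significant_blocks: float


def _pair_ld(
    X: np.ndarray, Y: np.ndarray, n_perm: int, rng: np.random.Generator,
    method: str,
) -> tuple[np.ndarray, np.ndarray]:
    """r² and P matrices for dosage matrices (rows = shared individuals)."""
    n = X.shape[0]

    def corr2(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        sa = Ac.std(axis=0)
        sb = Bc.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Ac.T @ Bc) / n / np.outer(sa, sb)
        return r**2

    r2 = corr2(X, Y)
    r2[~np.isfinite(r2)] = np.nan
    if method == "chi2":
        p = stats.chi2.sf(n * r2, df=1)
    else:
        exceed = np.zeros_like(r2)
        valid = np.isfinite(r2)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r2p = corr2(X, Y[perm])
            exceed += np.where(valid & (r2p >= r2 - 1e-12), 1.0, 0.0)
        p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.where(np.isfinite(r2), p, np.nan)
    return r2, p


def ld_scan(
    gt: GenotypeTable,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    method: Literal["permutation", "chi2"] = "permutation",
) -> LDResult:
    """Scan all locus pairs for allele-level composite LD.

    For every ordered allele pair (a at the first locus, b at the second)
    the squared composite correlation of dosages is computed on the
    individuals genotyped at both loci (pairwise deletion of missing
    calls); zero-variance alleles are skipped.  Locus-level r² is the
    ``p_a·p_b``-weighted mean over evaluable allele pairs; the locus-pair
    P value is the Bonferroni-adjusted minimum allele-pair P.
    """
    if method == "permutation" and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for a permutation test")
    rng = np.random.default_rng(seed)
    polymorphic = []
    for locus in gt.loci:
        try:
            if len(set(gt.alleles_at(locus))) >= 2:
                polymorphic.append(locus)
            else:
                logger.warning("locus %s is monomorphic; excluded from LD", locus)
        except ValueError:
            logger.warning("locus %s has no data; excluded from LD", locus)
    if len(polymorphic) < 2:
        raise ValueError("LD scan requires at least 2 polymorphic loci")

    dosages = {loc: gt.dosage_matrix(loc) for loc in polymorphic}
    allele_r2: dict[tuple[str, str], pd.DataFrame] = {}
    allele_p: dict[tuple[str, str], pd.DataFrame] = {}
    locus_r2 = pd.DataFrame(np.nan, index=polymorphic, columns=polymorphic)
    locus_p = pd.DataFrame(np.nan, index=polymorphic, columns=polymorphic)
    np.fill_diagonal(locus_r2.values, 1.0)
    np.fill_diagonal(locus_p.values, 1.0)

    n_sig_locus = n_locus = 0
    n_sig_block = n_block = 0
    for la, lb in itertools.combinations(polymorphic, 2):
        A, B = dosages[la], dosages[lb]
        mask = A.notna().all(axis=1) & B.notna().all(axis=1)
        if mask.sum() < 3:
            logger.warning("fewer than 3 shared individuals for %s/%s", la, lb)
            continue
        X = A.loc[mask].to_numpy()
        Y = B.loc[mask].to_numpy()
        r2, p = _pair_ld(X, Y, n_perm, rng, method)
        df_r2 = pd.DataFrame(r2, index=A.columns, columns=B.columns)
        df_p = pd.DataFrame(p, index=A.columns, columns=B.columns)
        allele_r2[(la, lb)] = df_r2
        allele_p[(la, lb)] = df_p

        freqs_a = X.mean(axis=0) / 2.0
        freqs_b = Y.mean(axis=0) / 2.0
        w = np.outer(freqs_a, freqs_b)
        valid = np.isfinite(r2)
        if valid.any():
            locus_r2.loc[la, lb] = locus_r2.loc[lb, la] = (
                float((r2[valid] * w[valid]).sum() / w[valid].sum())
            )
            n_tests = int(valid.sum())
            p_min = float(np.nanmin(p))
            p_loc = min(1.0, p_min * n_tests)
            locus_p.loc[la, lb] = locus_p.loc[lb, la] = p_loc
            n_locus += 1
            if p_loc <= alpha:
                n_sig_locus += 1
            n_block += n_tests
            n_sig_block += int((p[valid] <= alpha).sum())

    pct_locus = 100.0 * n_sig_locus / n_locus if n_locus else 0.0
    pct_block = 100.0 * n_sig_block / n_block if n_block else 0.0
    return LDResult(
        loci=tuple(polymorphic),
        allele_r2=allele_r2,
        allele_p=allele_p,
        locus_r2=locus_r2,
        locus_p=locus_p,
        alpha=alpha,
        pct_significant_locus_pairs=pct_locus,
        pct_significant_blocks=pct_block,
    )


def export_p_matrix(ld: LDResult, path: str | Path) -> None:
    """Write the locus × locus P matrix (6 dp) with a significance-star column.

    The matrix is square and symmetric with unit diagonal; the companion
    ``stars`` column marks loci involved in at least one pair significant
    at the scan's alpha.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("locus\t" + "\t".join(ld.loci) + "\tstars\n")
        for la in ld.loci:
            cells = [la]
            any_sig = False
            for lb in ld.loci:
                v = ld.locus_p.loc[la, lb]
                cells.append("NA" if pd.isna(v) else f"{v:.6f}")
                if la != lb and not pd.isna(v) and v <= ld.alpha:
                    any_sig = True
            cells.append("*" if any_sig else "")
            fh.write("\t".join(cells) + "\n")
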