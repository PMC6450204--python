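"""Microsatellite genotype model: allele frequencies, genotyping-error channel,
Mendelian transmission likelihoods and duplicate-based error-rate estimation.

Genotypes are unordered pairs of integer allele labels (e.g. fragment sizes).
The genotyping-error channel has two stages applied per locus:

1. *Allelic dropout* (rate ``e1``): a heterozygote ``(a, b)`` is observed as
   an apparent homozygote ``(a, a)`` or ``(b, b)``, each with probability
   ``e1``; true homozygotes are unaffected.  ``e1 < 0.5`` is required so the
   stage is a proper distribution.
2. *False alleles / stochastic miscall* (rate ``e2``): each surviving allele
   is independently replaced, with probability ``e2``, by an allele drawn
   from the population allele frequencies (possibly itself).

All transition matrices are enumerated exactly per locus, so likelihoods are
closed-form, and the same channel drives both simulation and inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

Genotype = tuple[int, int]  # canonical: a1 <= a2


class GenotypeError(ValueError):
    """Raised for malformed genotype data or panel configuration."""


def canonical(pair: Sequence[int]) -> Genotype:
    a, b = int(pair[0]), int(pair[1])
    return (a, b) if a <= b else (b, a)


@dataclass
class Locus:
    """One microsatellite locus: allele labels, frequencies and error rates."""

    name: str
    alleles: list[int]
    freqs: np.ndarray
    e1: float = 0.01
    e2: float = 0.01
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.alleles = [int(a) for a in self.alleles]
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.alleles) != len(set(self.alleles)):
            raise GenotypeError(f"locus {self.name}: duplicate allele labels")
        if self.freqs.shape != (len(self.alleles),):
            raise GenotypeError(f"locus {self.name}: freqs/alleles length mismatch")
        if np.any(self.freqs < 0) or abs(self.freqs.sum() - 1.0) > 1e-9:
            raise GenotypeError(f"locus {self.name}: frequencies must be >=0 and sum to 1")
        if not (0 <= self.e1 < 0.5):
            raise GenotypeError(f"locus {self.name}: e1 must be in [0, 0.5)")
        if not (0 <= self.e2 < 1):
            raise GenotypeError(f"locus {self.name}: e2 must be in [0, 1)")

    # -- enumeration machinery ------------------------------------------------

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def allele_index(self) -> dict[int, int]:
        if "aidx" not in self._cache:
            self._cache["aidx"] = {a: i for i, a in enumerate(self.alleles)}
        return self._cache["aidx"]

    @property
    def genotypes(self) -> list[tuple[int, int]]:
        """All unordered allele-index pairs (i <= j)."""
        if "gts" not in self._cache:
            k = self.n_alleles
            self._cache["gts"] = [(i, j) for i in range(k) for j in range(i, k)]
        return self._cache["gts"]

    @property
    def genotype_index(self) -> dict[tuple[int, int], int]:
        if "gidx" not in self._cache:
            self._cache["gidx"] = {g: n for n, g in enumerate(self.genotypes)}
        return self._cache["gidx"]

    def encode(self, gt: Genotype | None) -> int:
        """Map an allele-label genotype to its index; -1 encodes missing."""
        if gt is None:
            return -1
        a, b = canonical(gt)
        try:
            i, j = self.allele_index[a], self.allele_index[b]
        except KeyError as exc:
            raise GenotypeError(f"locus {self.name}: unknown allele {exc.args[0]}") from None
        if i > j:  # canonicalize on indices: the allele list may be unsorted
            i, j = j, i
        return self.genotype_index[(i, j)]

    def decode(self, idx: int) -> Genotype | None:
        if idx < 0:
            return None
        i, j = self.genotypes[idx]
        return (self.alleles[i], self.alleles[j])

    @property
    def hw(self) -> np.ndarray:
        """Hardy-Weinberg genotype probabilities, indexed like `genotypes`."""
        if "hw" not in self._cache:
            p = self.freqs
            out = np.array(
                [p[i] ** 2 if i == j else 2 * p[i] * p[j] for i, j in self.genotypes]
            )
            self._cache["hw"] = out
        return self._cache["hw"]

    def _gamete(self, g: int) -> np.ndarray:
        """Transmission distribution over alleles for genotype index g."""
        i, j = self.genotypes[g]
        v = np.zeros(self.n_alleles)
        v[i] += 0.5
        v[j] += 0.5
        return v

    @property
    def mendel(self) -> np.ndarray:
        """T[d, s, c] = P(true cub genotype c | dam genotype d, sire genotype s)."""
        if "mendel" not in self._cache:
            gts = self.genotypes
            ng = len(gts)
            gam = np.stack([self._gamete(g) for g in range(ng)])  # (ng, k)
            T = np.zeros((ng, ng, ng))
            for c, (x, y) in enumerate(gts):
                if x == y:
                    T[:, :, c] = np.outer(gam[:, x], gam[:, y])
                else:
                    T[:, :, c] = np.outer(gam[:, x], gam[:, y]) + np.outer(gam[:, y], gam[:, x])
            self._cache["mendel"] = T
        return self._cache["mendel"]

    @property
    def mendel_one(self) -> np.ndarray:
        """M1[d, c] = P(true cub c | one parent d, other parent unsampled (HW))."""
        if "mendel1" not in self._cache:
            self._cache["mendel1"] = np.einsum("dsc,s->dc", self.mendel, self.hw)
        return self._cache["mendel1"]

    @property
    def error_matrix(self) -> np.ndarray:
        """E[t, o] = P(observed genotype o | true genotype t) under the channel."""
        if "emat" not in self._cache:
            gts = self.genotypes
            gidx = self.genotype_index
            ng = len(gts)
            e1, e2, p = self.e1, self.e2, self.freqs
            # dropout stage
            D = np.zeros((ng, ng))
            for t, (i, j) in enumerate(gts):
                if i == j:
                    D[t, t] = 1.0
                else:
                    D[t, gidx[(i, i)]] += e1
                    D[t, gidx[(j, j)]] += e1
                    D[t, t] += 1.0 - 2 * e1
            # per-allele miscall channel
            A = (1 - e2) * np.eye(self.n_alleles) + e2 * np.tile(p, (self.n_alleles, 1))
            C = np.zeros((ng, ng))
            for t, (x, y) in enumerate(gts):
                for o, (u, v) in enumerate(gts):
                    if u == v:
                        C[t, o] = A[x, u] * A[y, v]
                    else:
                        C[t, o] = A[x, u] * A[y, v] + A[x, v] * A[y, u]
            self._cache["emat"] = D @ C
        return self._cache["emat"]

    @property
    def obs_like(self) -> np.ndarray:
        """OL[d, s, o] = P(observed cub o | dam d, sire s), both parents sampled."""
        if "ol" not in self._cache:
            ng = len(self.genotypes)
            self._cache["ol"] = (self.mendel.reshape(ng * ng, ng) @ self.error_matrix).reshape(
                ng, ng, ng
            )
        return self._cache["ol"]

    @property
    def obs_like_one(self) -> np.ndarray:
        """OL1[d, o]: one parent sampled, the other integrated over HW."""
        if "ol1" not in self._cache:
            self._cache["ol1"] = self.mendel_one @ self.error_matrix
        return self._cache["ol1"]

    @property
    def obs_like_none(self) -> np.ndarray:
        """OL0[o]: both parents unsampled -> HW marginal pushed through the channel."""
        if "ol0" not in self._cache:
            self._cache["ol0"] = self.hw @ self.error_matrix
        return self._cache["ol0"]


class LocusPanel:
    """Ordered collection of loci with frequencies and error rates."""

    def __init__(self, loci: Iterable[Locus]):
        self.loci: list[Locus] = list(loci)
        if not self.loci:
            raise GenotypeError("panel must contain at least one locus")
        names = [l.name for l in self.loci]
        if len(names) != len(set(names)):
            raise GenotypeError("duplicate locus names in panel")
        self._by_name = {l.name: l for l in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, name: str) -> Locus:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def expected_heterozygosity(self) -> pd.Series:
        """Per-locus He = 1 - sum(p^2)."""
        return pd.Series(
            {l.name: 1.0 - float(np.sum(l.freqs**2)) for l in self.loci}, name="He"
        )

    # -- persistence ----------------------------------------------------------

    def to_csv(self, path) -> None:
        rows = []
        for l in self.loci:
            for a, f in zip(l.alleles, l.freqs):
                rows.append({"locus": l.name, "allele": a, "freq": f, "e1": l.e1, "e2": l.e2})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LocusPanel":
        df = pd.read_csv(path)
        required = {"locus", "allele", "freq"}
        if not required.issubset(df.columns):
            raise GenotypeError(f"panel file must have columns {sorted(required)}")
        loci = []
        for name, grp in df.groupby("locus", sort=False):
            e1 = float(grp["e1"].iloc[0]) if "e1" in grp else 0.01
            e2 = float(grp["e2"].iloc[0]) if "e2" in grp else 0.01
            loci.append(
                Locus(str(name), grp["allele"].tolist(), grp["freq"].to_numpy(), e1=e1, e2=e2)
            )
        return cls(loci)


class GenotypeTable:
    """Mapping individual -> locus -> canonical unordered allele pair (or None)."""

    def __init__(self, data: Mapping[str, Mapping[str, Genotype | None]], loci: Sequence[str]):
        self.loci = list(loci)
        self.data: dict[str, dict[str, Genotype | None]] = {}
        for ind, gts in data.items():
            row: dict[str, Genotype | None] = {}
            for loc in self.loci:
                gt = gts.get(loc)
                row[loc] = None if gt is None else canonical(gt)
            self.data[str(ind)] = row

    @property
    def individuals(self) -> list[str]:
        return list(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, ind: str) -> bool:
        return ind in self.data

    def get(self, ind: str, locus: str) -> Genotype | None:
        return self.data[ind][locus]

    def genotypes_of(self, ind: str) -> dict[str, Genotype | None]:
        return self.data[ind]

    def subset(self, individuals: Iterable[str]) -> "GenotypeTable":
        return GenotypeTable({i: self.data[i] for i in individuals if i in self.data}, self.loci)

    # -- wide CSV (id, <locus>_a1, <locus>_a2, ...) ---------------------------

    def to_wide(self) -> pd.DataFrame:
        rows = []
        for ind, gts in self.data.items():
            row: dict[str, object] = {"id": ind}
            for loc in self.loci:
                gt = gts[loc]
                row[f"{loc}_a1"] = gt[0] if gt else pd.NA
                row[f"{loc}_a2"] = gt[1] if gt else pd.NA
            rows.append(row)
        return pd.DataFrame(rows)

    def to_wide_csv(self, path) -> None:
        self.to_wide().to_csv(path, index=False)

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "GenotypeTable":
        loci = []
        for c in df.columns:
            if c.endswith("_a1"):
                loci.append(c[:-3])
        data: dict[str, dict[str, Genotype | None]] = {}
        for _, r in df.iterrows():
            gts: dict[str, Genotype | None] = {}
            for loc in loci:
                a1, a2 = r[f"{loc}_a1"], r[f"{loc}_a2"]
                gts[loc] = None if pd.isna(a1) or pd.isna(a2) else canonical((int(a1), int(a2)))
            data[str(r["id"])] = gts
        return cls(data, loci)

    @classmethod
    def from_wide_csv(cls, path) -> "GenotypeTable":
        return cls.from_wide(pd.read_csv(path))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def allele_frequencies(genotypes: GenotypeTable) -> pd.DataFrame:
    """Per-locus allele frequencies by direct gene counting.

    Both alleles of every non-missing genotype contribute; missing entries are
    ignored.  Raises if a locus has no observed genotypes at all.
    """
    rows = []
    for loc in genotypes.loci:
        counts: dict[int, int] = {}
        for ind in genotypes.individuals:
            gt = genotypes.get(ind, loc)
            if gt is None:
                continue
            for a in gt:
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            raise GenotypeError(f"locus {loc}: no non-missing genotypes")
        total = sum(counts.values())
        for a in sorted(counts):
            rows.append({"locus": loc, "allele": a, "freq": counts[a] / total})
    return pd.DataFrame(rows)


def panel_from_genotypes(
    genotypes: GenotypeTable, e1: float = 0.01, e2: float = 0.01
) -> LocusPanel:
    """Build a LocusPanel with observed allele frequencies and given error rates."""
    freqs = allele_frequencies(genotypes)
    loci = []
    for loc, grp in freqs.groupby("locus", sort=False):
        loci.append(Locus(str(loc), grp["allele"].tolist(), grp["freq"].to_numpy(), e1=e1, e2=e2))
    return LocusPanel(loci)


def error_likelihood(
    observed: Genotype | None, true: Genotype, locus: Locus
) -> float:
    """P(observed genotype | true genotype) under the dropout-then-miscall channel.

    A missing observation is uninformative and contributes likelihood 1.
    """
    if observed is None:
        return 1.0
    t = locus.encode(true)
    o = locus.encode(observed)
    return float(locus.error_matrix[t, o])


def transmission_likelihood(
    cub: Mapping[str, Genotype | None],
    dam: Mapping[str, Genotype | None] | None,
    sire: Mapping[str, Genotype | None] | None,
    panel: LocusPanel,
) -> float:
    """Multilocus P(observed cub genotype | parents) under Mendelian segregation
    plus the genotyping-error channel.

    ``dam``/``sire`` may be ``None`` (unsampled parent): their gametes are then
    integrated over the panel allele frequencies under Hardy-Weinberg.  A
    parent's missing single locus is handled the same way, and a missing cub
    locus contributes factor 1.
    """
    out = 1.0
    for locus in panel:
        go = cub.get(locus.name)
        if go is None:
            continue
        o = locus.encode(go)
        gd = None if dam is None else dam.get(locus.name)
        gs = None if sire is None else sire.get(locus.name)
        if gd is not None and gs is not None:
            out *= locus.obs_like[locus.encode(gd), locus.encode(gs), o]
        elif gd is not None:
            out *= locus.obs_like_one[locus.encode(gd), o]
        elif gs is not None:
            out *= locus.obs_like_one[locus.encode(gs), o]
        else:
            out *= locus.obs_like_none[o]
    return float(out)


def mismatch_count(
    cub: Mapping[str, Genotype | None], candidate: Mapping[str, Genotype | None]
) -> int:
    """Number of loci at which cub and candidate parent share no allele.

    Loci missing in either individual are skipped.  This is the exclusion
    count to which the assignment mismatch tolerance applies.
    """
    n = 0
    for loc, gt_c in cub.items():
        if gt_c is None:
            continue
        gt_p = candidate.get(loc)
        if gt_p is None:
            continue
        if not (set(gt_c) & set(gt_p)):
            n += 1
    return n


# ---------------------------------------------------------------------------
# duplicate-genotype estimation of e1/e2
# ---------------------------------------------------------------------------


def _pair_loglik(e1: float, e2: float, locus: Locus, pairs: list[tuple[int, int]]) -> float:
    """Log-likelihood of replicate genotype pairs under shared (e1, e2).

    Each replicate is an independent pass of the error channel applied to the
    same (latent) true genotype, whose prior is Hardy-Weinberg at the panel
    frequencies.
    """
    work = Locus(locus.name, locus.alleles, locus.freqs, e1=e1, e2=e2)
    E = work.error_matrix
    hw = work.hw
    ll = 0.0
    for o1, o2 in pairs:
        p = float(hw @ (E[:, o1] * E[:, o2]))
        ll += np.log(max(p, 1e-300))
    return ll


def estimate_error_rates(
    duplicates: Mapping[str, list[tuple[Genotype | None, Genotype | None]]],
    panel: LocusPanel,
) -> pd.DataFrame:
    """Per-locus ML estimates of (e1, e2) from replicate genotypings.

    Parameters
    ----------
    duplicates
        locus name -> list of (replicate1, replicate2) genotype pairs for the
        same DNA sample; pairs with a missing replicate are skipped.
    panel
        supplies allele lists and frequencies (the error rates stored on the
        panel are ignored).

    Returns a frame with columns locus, e1, e2, n_pairs, n_discordant and a
    final ``pooled`` row maximizing the summed log-likelihood across loci.
    If a locus shows no discordance the estimates are 0 and ``flat_likelihood``
    is set (with a warning).
    """
    rows = []
    encoded_all: dict[str, list[tuple[int, int]]] = {}
    for locus in panel:
        raw = duplicates.get(locus.name, [])
        pairs = []
        n_disc = 0
        for g1, g2 in raw:
            if g1 is None or g2 is None:
                continue
            o1, o2 = locus.encode(g1), locus.encode(g2)
            pairs.append((o1, o2))
            if o1 != o2:
                n_disc += 1
        if not pairs:
            continue
        encoded_all[locus.name] = pairs
        flat = n_disc == 0
        if flat:
            warnings.warn(
                f"locus {locus.name}: no discordant duplicate pairs; e1=e2=0 reported",
                stacklevel=2,
            )
            e1_hat, e2_hat = 0.0, 0.0
        else:
            e1_hat, e2_hat = _ml_rates(locus, pairs)
        rows.append(
            {
                "locus": locus.name,
                "e1": e1_hat,
                "e2": e2_hat,
                "n_pairs": len(pairs),
                "n_discordant": n_disc,
                "flat_likelihood": flat,
            }
        )
    if not rows:
        raise GenotypeError("no usable duplicate pairs at any locus")
    # pooled estimate across loci (shared e1, e2)
    def neg_pooled(x):
        return -sum(
            _pair_loglik(x[0], x[1], panel[name], prs) for name, prs in encoded_all.items()
        )

    res = _grid_refine(neg_pooled)
    rows.append(
        {
            "locus": "pooled",
            "e1": res[0],
            "e2": res[1],
            "n_pairs": sum(r["n_pairs"] for r in rows),
            "n_discordant": sum(r["n_discordant"] for r in rows),
            "flat_likelihood": all(r["flat_likelihood"] for r in rows),
        }
    )
    return pd.DataFrame(rows)


def _ml_rates(locus: Locus, pairs: list[tuple[int, int]]) -> tuple[float, float]:
    def neg(x):
        return -_pair_loglik(x[0], x[1], locus, pairs)

    return _grid_refine(neg)


def _grid_refine(neg_loglik) -> tuple[float, float]:
    """Coarse grid search then bounded quasi-Newton refinement."""
    grid = [0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3]
    best, best_val = (0.01, 0.01), np.inf
    for a in grid:
        for b in grid:
            v = neg_loglik((a, b))
            if v < best_val:
                best, best_val = (a, b), v
    res = minimize(
        neg_loglik,
        x0=np.array(best),
        method="L-BFGS-B",
        bounds=[(0.0, 0.49), (0.0, 0.95)],
    )
    x = res.x if res.fun <= best_val else np.array(best)
    return float(x[0]), float(x[1])
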