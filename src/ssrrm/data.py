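"""Core data containers for the longitudinal single-step GWAS pipeline.

The pipeline operates on four kinds of objects:

* :class:`Pedigree` -- ordered animal/sire/dam triples (0 = unknown parent),
  the basis of every pedigree relationship matrix.
* :class:`PhenotypeTable` -- long-format repeated records
  ``(animal, age_months, value, herd_year, birth_month)``.
* :class:`GenotypePanel` -- biallelic SNP dosages in {0, 1, 2} with a marker
  map and allele frequencies.
* :class:`CovarianceComponents` -- the random-regression variance structure:
  3x3 additive (V_g) and permanent-environment (V_p) coefficient covariances
  plus age-class residual variances.

All containers are plain-text round-trippable (CSV/TSV) so that simulated
datasets, intermediate artifacts and results stay human-inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN_PARENT = 0
MISSING_DOSAGE = -1

AGE_MIN = 0
AGE_MAX = 60


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    frame
        DataFrame with integer columns ``animal``, ``sire``, ``dam`` (0 for an
        unknown parent) and optionally ``generation`` and ``sex`` ("M"/"F").
        Parents must precede offspring.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        for col in ("animal", "sire", "dam"):
            _require(col in df.columns, f"pedigree frame is missing column {col!r}")
            df[col] = df[col].astype(np.int64)
        ids = df["animal"].to_numpy()
        _require(len(np.unique(ids)) == len(ids), "duplicate animal ids in pedigree")
        self._pos = {int(a): i for i, a in enumerate(ids)}
        sire_idx = np.full(len(df), -1, dtype=np.int64)
        dam_idx = np.full(len(df), -1, dtype=np.int64)
        for i, (a, s, d) in enumerate(zip(ids, df["sire"], df["dam"])):
            for which, p, out in (("sire", int(s), sire_idx), ("dam", int(d), dam_idx)):
                if p == UNKNOWN_PARENT:
                    continue
                if p not in self._pos:
                    raise ValueError(f"{which} {p} of animal {int(a)} not in pedigree")
                j = self._pos[p]
                if j >= i:
                    raise ValueError(
                        f"pedigree not topologically ordered: {which} {p} "
                        f"listed at/after offspring {int(a)}"
                    )
                out[i] = j
        sires = set(df.loc[df["sire"] != UNKNOWN_PARENT, "sire"])
        dams = set(df.loc[df["dam"] != UNKNOWN_PARENT, "dam"])
        _require(not (sires & dams), "animals appearing as both sire and dam")
        self.frame = df
        self.sire_idx = sire_idx
        self.dam_idx = dam_idx

    # -- basic queries ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_animals(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["animal"].to_numpy()

    def indices(self, animals) -> np.ndarray:
        """Positions of ``animals`` in pedigree order (raises on unknown id)."""
        out = np.empty(len(animals), dtype=np.int64)
        for k, a in enumerate(animals):
            try:
                out[k] = self._pos[int(a)]
            except KeyError:
                raise KeyError(f"animal {a} not in pedigree") from None
        return out

    def __contains__(self, animal) -> bool:
        return int(animal) in self._pos

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        try:
            frame = pd.read_csv(path)
            return cls(frame)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cannot parse pedigree file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Long-format longitudinal records.

    Ages are integer months in [0, 60]; fractional ages are floored on
    construction (records are reported monthly).
    """

    frame: pd.DataFrame

    COLUMNS = ("animal", "age_months", "value", "herd_year", "birth_month")

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        for col in self.COLUMNS:
            _require(col in df.columns, f"phenotype frame is missing column {col!r}")
        df["animal"] = df["animal"].astype(np.int64)
        df["age_months"] = np.floor(df["age_months"].to_numpy(dtype=float)).astype(np.int64)
        df["value"] = df["value"].astype(float)
        ages = df["age_months"].to_numpy()
        _require(
            bool(np.all((ages >= AGE_MIN) & (ages <= AGE_MAX))),
            f"ages must lie in [{AGE_MIN}, {AGE_MAX}] months",
        )
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def animals(self) -> np.ndarray:
        """Unique animal ids, in order of first appearance."""
        return self.frame["animal"].unique()

    def check_against_pedigree(self, pedigree: Pedigree) -> None:
        missing = [a for a in self.animals if a not in pedigree]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped animals absent from pedigree "
                f"(first: {missing[:5]})"
            )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """SNP dosages (0/1/2, -1 = missing) for the genotyped subset.

    ``snp_map`` has columns ``snp_id``, ``chrom``, ``pos``. ``allele_freq``
    holds per-SNP frequencies of the counted allele computed from non-missing
    dosages (``p = mean(dosage)/2``); ``founder_freq`` optionally carries the
    frequencies the simulator drew founders from (used for "supplied"
    centering).
    """

    animal_ids: np.ndarray
    dosages: np.ndarray
    snp_map: pd.DataFrame
    allele_freq: np.ndarray | None = None
    founder_freq: np.ndarray | None = None
    haplotypes: np.ndarray | None = None  # (n, m, 2) gametes, simulation only
    transmissions: np.ndarray | None = None  # (n, m, 2) parental-gamete choice

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        _require(n == len(self.animal_ids), "dosage rows != number of animals")
        _require(m == len(self.snp_map), "dosage columns != map length")
        for col in ("snp_id", "chrom", "pos"):
            _require(col in self.snp_map.columns, f"snp_map missing column {col!r}")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING_DOSAGE))
        _require(bool(valid.all()), "dosages must be 0/1/2 or -1 (missing)")
        if self.allele_freq is None:
            self.allele_freq = self.observed_frequencies()
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING_DOSAGE).mean(axis=0)

    def observed_frequencies(self) -> np.ndarray:
        """Counted-allele frequency per SNP from non-missing dosages."""
        d = np.ma.masked_equal(self.dosages, MISSING_DOSAGE)
        p = d.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(p, dtype=float)

    def imputed_dosages(self, freq: np.ndarray | None = None) -> np.ndarray:
        """Float dosage matrix with missing entries replaced by ``2 p_o``."""
        p = self.allele_freq if freq is None else np.asarray(freq, dtype=float)
        out = self.dosages.astype(float)
        miss = self.dosages == MISSING_DOSAGE
        if miss.any():
            out[miss] = np.broadcast_to(2.0 * p, out.shape)[miss]
        return out

    def centered_matrix(self, freq: np.ndarray | None = None) -> np.ndarray:
        """Centered marker matrix W = (imputed dosage) - 2p."""
        p = self.allele_freq if freq is None else np.asarray(freq, dtype=float)
        return self.imputed_dosages(p) - 2.0 * p

    def subset_snps(self, mask) -> "GenotypePanel":
        mask = np.asarray(mask)
        return GenotypePanel(
            animal_ids=self.animal_ids,
            dosages=self.dosages[:, mask],
            snp_map=self.snp_map.loc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.snp_map.iloc[mask].reset_index(drop=True),
            founder_freq=None if self.founder_freq is None else self.founder_freq[mask],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, mask],
            transmissions=None
            if self.transmissions is None
            else self.transmissions[:, mask],
        )

    def subset_animals(self, animals) -> "GenotypePanel":
        pos = {int(a): i for i, a in enumerate(self.animal_ids)}
        idx = np.array([pos[int(a)] for a in animals], dtype=np.int64)
        return GenotypePanel(
            animal_ids=self.animal_ids[idx],
            dosages=self.dosages[idx],
            snp_map=self.snp_map.copy(),
            founder_freq=self.founder_freq,
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            transmissions=None if self.transmissions is None else self.transmissions[idx],
        )

    # -- I/O ----------------------------------------------------------------

    def to_dosage_tsv(self, dosage_path, map_path) -> None:
        df = pd.DataFrame(
            self.dosages, columns=self.snp_map["snp_id"].tolist(), copy=False
        )
        df.insert(0, "animal", self.animal_ids)
        df.to_csv(dosage_path, sep="\t", index=False)
        self.snp_map.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_dosage_tsv(cls, dosage_path, map_path) -> "GenotypePanel":
        df = pd.read_csv(dosage_path, sep="\t")
        snp_map = pd.read_csv(map_path, sep="\t")
        animals = df["animal"].to_numpy(dtype=np.int64)
        dosages = df.drop(columns="animal").to_numpy(dtype=np.int8)
        return cls(animal_ids=animals, dosages=dosages, snp_map=snp_map)

    def to_plink(self, prefix) -> None:
        """Write PLINK-style .ped/.map text files (alleles coded A/B)."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, animal in enumerate(self.animal_ids):
                row = [str(animal), str(animal), "0", "0", "0", "-9"]
                for d in self.dosages[i]:
                    row.extend(
                        {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B")}.get(
                            int(d), ("0", "0")
                        )
                    )
                fh.write(" ".join(row) + "\n")
        with open(prefix.with_suffix(".map"), "w") as fh:
            for _, r in self.snp_map.iterrows():
                fh.write(f"{r['chrom']} {r['snp_id']} 0 {r['pos']}\n")

    @classmethod
    def from_plink(cls, prefix) -> "GenotypePanel":
        prefix = Path(prefix)
        rows = []
        with open(prefix.with_suffix(".map")) as fh:
            for line in fh:
                chrom, snp_id, _, pos = line.split()
                rows.append((snp_id, int(chrom), int(pos)))
        snp_map = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
        animals, dosages = [], []
        code = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2}
        with open(prefix.with_suffix(".ped")) as fh:
            for line in fh:
                parts = line.split()
                animals.append(int(parts[1]))
                alleles = parts[6:]
                d = [
                    code.get((alleles[2 * j], alleles[2 * j + 1]), MISSING_DOSAGE)
                    for j in range(len(snp_map))
                ]
                dosages.append(d)
        return cls(
            animal_ids=np.array(animals, dtype=np.int64),
            dosages=np.array(dosages, dtype=np.int8),
            snp_map=snp_map,
        )


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    _require(mat.ndim == 2 and mat.shape[0] == mat.shape[1], f"{name} must be square")
    _require(bool(np.allclose(mat, mat.T, atol=1e-12)), f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(f"{name} is not positive semidefinite (min eig {w.min():.3g})")
    return mat


def default_residual_bounds(n_classes: int = 6) -> np.ndarray:
    """Upper age bounds of the first ``n_classes - 1`` residual classes.

    The default is 6 classes of 10 months: [0,10), [10,20), ..., [50,60].
    """
    width = AGE_MAX / n_classes
    return np.arange(1, n_classes) * width


@dataclass
class CovarianceComponents:
    """RRM variance structure: V_g, V_p (k x k) and age-class residuals."""

    V_g: np.ndarray
    V_p: np.ndarray
    sigma_e2: np.ndarray
    class_bounds: np.ndarray = field(default_factory=default_residual_bounds)
    provenance: str = "fixed_input"

    def __post_init__(self) -> None:
        self.V_g = _check_psd(self.V_g, "V_g")
        self.V_p = _check_psd(self.V_p, "V_p")
        _require(self.V_g.shape == self.V_p.shape, "V_g and V_p must be same order")
        self.sigma_e2 = np.asarray(self.sigma_e2, dtype=float)
        self.class_bounds = np.asarray(self.class_bounds, dtype=float)
        _require(bool((self.sigma_e2 > 0).all()), "residual variances must be > 0")
        _require(
            len(self.sigma_e2) == len(self.class_bounds) + 1,
            "need one residual variance per age class",
        )

    @property
    def order(self) -> int:
        """Number of random-regression coefficients (3 for a quadratic RRM)."""
        return self.V_g.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.sigma_e2)

    def residual_class(self, ages) -> np.ndarray:
        return np.searchsorted(self.class_bounds, np.asarray(ages), side="right")

    def residual_variance(self, ages) -> np.ndarray:
        return self.sigma_e2[self.residual_class(ages)]

    # -- I/O ----------------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "V_g": self.V_g.tolist(),
            "V_p": self.V_p.tolist(),
            "sigma_e2": self.sigma_e2.tolist(),
            "class_bounds": self.class_bounds.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "CovarianceComponents":
        payload = json.loads(Path(path).read_text())
        return cls(
            V_g=np.array(payload["V_g"]),
            V_p=np.array(payload["V_p"]),
            sigma_e2=np.array(payload["sigma_e2"]),
            class_bounds=np.array(payload["class_bounds"]),
            provenance=payload.get("provenance", "fixed_input"),
        )
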