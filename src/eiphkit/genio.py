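"""Genotype containers and text-format I/O (PLINK PED/MAP and a TSV matrix dialect).

Genotypes are held as an individuals x SNPs matrix of minor-allele
counts {0, 1, 2} with NaN for missing, alongside a SNP map (chromosome,
1-based bp position, alleles).  The PED/MAP reader determines the minor
allele from the sample itself (ties broken lexicographically) so coding
is deterministic for any input file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MAP_COLUMNS = ["snp_id", "chromosome", "position", "allele_a", "allele_b"]


class PedParseError(ValueError):
    """Raised on malformed PED/MAP input; message names the offending line."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix.

    Attributes
    ----------
    calls : ndarray, shape (n_individuals, n_snps)
        Float codes 0/1/2 counting copies of ``allele_a`` (the minor
        allele at read time); NaN marks a missing call.
    individuals : list of str
        Ordered individual ids.
    sexes : ndarray of str
        Per-individual sex labels, 'M'/'F' ('U' if unknown).
    snp_map : DataFrame
        One row per SNP with columns snp_id, chromosome, position,
        allele_a, allele_b, aligned with the columns of ``calls``.
    """

    calls: np.ndarray
    individuals: list[str]
    snp_map: pd.DataFrame
    sexes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x snps)")
        n_ind, n_snp = self.calls.shape
        if len(self.individuals) != n_ind:
            raise ValueError("individuals length does not match calls rows")
        if len(self.snp_map) != n_snp:
            raise ValueError("snp_map length does not match calls columns")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("calls must be coded 0/1/2/NaN")
        if self.sexes is None:
            self.sexes = np.array(["U"] * n_ind)
        else:
            self.sexes = np.asarray(self.sexes, dtype=object)
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snp_map["snp_id"])

    def subset_snps(self, mask_or_ids) -> "GenotypeMatrix":
        """Return a new matrix restricted to a boolean mask or list of SNP ids."""
        if isinstance(mask_or_ids, (list, tuple, pd.Index)) and not (
            len(mask_or_ids) and isinstance(mask_or_ids[0], (bool, np.bool_))
        ):
            idx = self.snp_map.index[self.snp_map["snp_id"].isin(mask_or_ids)].to_numpy()
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids, dtype=bool))
        return replace(
            self,
            calls=self.calls[:, idx],
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True),
        )

    def subset_individuals(self, mask) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        return replace(
            self,
            calls=self.calls[idx, :],
            individuals=[self.individuals[i] for i in idx],
            sexes=self.sexes[idx],
        )

    def column(self, snp_id: str) -> np.ndarray:
        j = int(self.snp_map.index[self.snp_map["snp_id"] == snp_id][0])
        return self.calls[:, j]


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise PedParseError(f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}")
            rows.append((parts[1], parts[0], int(parts[3])))
    df = pd.DataFrame(rows, columns=["snp_id", "chromosome", "position"])
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise PedParseError(f"{map_path}: duplicate snp_id {dup}")
    return df


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read white-space-delimited PED/MAP files into a GenotypeMatrix.

    The minor allele at each SNP is determined from the sample (ties
    broken lexicographically) and becomes ``allele_a``; "0 0" is
    missing.  Non-biallelic SNPs raise :class:`PedParseError`.
    """
    snp_map = _read_map(map_path)
    m = len(snp_map)
    individuals, sexes, allele_rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            individuals.append(parts[1])
            sexes.append({"1": "M", "2": "F"}.get(parts[4], "U"))
            allele_rows.append(parts[6:])
    n = len(individuals)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2)

    calls = np.full((n, m), np.nan)
    allele_a, allele_b = [], []
    for j in range(m):
        col = alleles[:, j, :]
        flat = col.ravel()
        observed = sorted(set(flat) - {"0"})
        if len(observed) > 2:
            raise PedParseError(
                f"{ped_path}: SNP {snp_map['snp_id'][j]} has >2 alleles: {observed}"
            )
        if not observed:
            allele_a.append("0")
            allele_b.append("0")
            continue
        missing = (col == "0").any(axis=1)
        if len(observed) == 1:
            # monomorphic: minor allele unobserved, all dosages 0
            allele_a.append("0")
            allele_b.append(observed[0])
            dose = np.zeros(n)
            dose[missing] = np.nan
            calls[:, j] = dose
            continue
        counts = {a: int(np.sum(flat == a)) for a in observed}
        # minor allele: lowest count, lexicographic tie-break
        order = sorted(observed, key=lambda a: (counts[a], a))
        minor, major = order[0], order[1]
        allele_a.append(minor)
        allele_b.append(major)
        dose = (col == minor).sum(axis=1).astype(float)
        dose[missing] = np.nan
        calls[:, j] = dose

    snp_map = snp_map.assign(allele_a=allele_a, allele_b=allele_b)
    return GenotypeMatrix(calls=calls, individuals=individuals,
                          snp_map=snp_map[MAP_COLUMNS], sexes=np.array(sexes, dtype=object))


def write_ped_map(matrix: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP text files; inverse of :func:`read_ped_map` on valid data."""
    sm = matrix.snp_map
    with open(map_path, "w") as fh:
        for _, r in sm.iterrows():
            fh.write(f"{r['chromosome']}\t{r['snp_id']}\t0\t{int(r['position'])}\n")
    sex_code = {"M": "1", "F": "2", "U": "0"}
    a = sm["allele_a"].to_numpy()
    b = sm["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(matrix.individuals):
            fields = [ind, ind, "0", "0", sex_code.get(str(matrix.sexes[i]), "0"), "-9"]
            row = matrix.calls[i]
            for j, g in enumerate(row):
                if np.isnan(g):
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [a[j], a[j]]
                elif g == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(fields) + "\n")


def write_matrix_tsv(matrix: GenotypeMatrix, matrix_path, map_path) -> None:
    """Internal TSV dialect: rows = SNPs, columns = individuals, codes 0/1/2/NA."""
    df = pd.DataFrame(matrix.calls.T, index=matrix.snp_map["snp_id"],
                      columns=matrix.individuals)
    df.to_csv(matrix_path, sep="\t", na_rep="NA", index_label="snp_id",
              float_format="%.0f")
    matrix.snp_map.to_csv(map_path, sep="\t", index=False)
    # per-individual sexes ride in a sidecar next to the map
    sex_path = Path(str(map_path) + ".ind")
    pd.DataFrame({"individual": matrix.individuals, "sex": matrix.sexes}).to_csv(
        sex_path, sep="\t", index=False
    )


def read_matrix_tsv(matrix_path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values="NA")
    snp_map = pd.read_csv(map_path, sep="\t")
    sex_path = Path(str(map_path) + ".ind")
    if sex_path.exists():
        ind = pd.read_csv(sex_path, sep="\t")
        sexes = ind["sex"].to_numpy(dtype=object)
    else:
        sexes = None
    return GenotypeMatrix(calls=df.to_numpy().T, individuals=list(df.columns),
                          snp_map=snp_map[MAP_COLUMNS], sexes=sexes)
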