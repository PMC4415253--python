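"""Genotype and phenotype containers, standardization, and flat-file I/O.

Genotypes are additive allele dosages (0/1/2 copies of the counted allele)
for ``n`` individuals at ``m`` biallelic markers.  All regression models in
this package operate on the column-standardized design matrix

    Z_i = (x_i - 2 p_i) / sqrt(2 p_i (1 - p_i)),

where ``p_i`` is the allele frequency of marker ``i``.  Standardization puts
every marker on a unit-variance scale (under Hardy-Weinberg proportions) so
that per-marker effect variances are directly comparable with the total
genetic variance.

Supported formats: PLINK 1.9 ``--recode A`` (``.raw``) files, plain TSV
dosage tables, and two-column phenotype TSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing dosage

__all__ = [
    "GenotypeMatrix",
    "StandardizedGenotypes",
    "PhenotypeVector",
    "compute_allele_frequencies",
    "standardize",
    "read_plink_raw",
    "write_plink_raw",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
]


def _check_unique(ids, what):
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for x in ids:
            if x in seen:
                dup = x
                break
            seen.add(x)
        raise ValueError(f"duplicated {what} id: {dup!r}")


@dataclass
class GenotypeMatrix:
    """Raw allele-count genotypes with sample and marker identifiers.

    ``dosages`` is an ``n x m`` integer array with entries in ``{0, 1, 2}``
    or :data:`MISSING` (``-1``) for a missing call.  ``counted_alleles``
    optionally records which allele the dosage counts (from PLINK headers).
    """

    sample_ids: list
    marker_ids: list
    dosages: np.ndarray
    counted_alleles: list | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if m != len(self.marker_ids):
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.marker_ids, "marker")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage {self.dosages[i, j]!r} at sample {self.sample_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r} is not in {{0, 1, 2}} or missing"
            )

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.marker_ids),
            self.dosages[idx],
            self.counted_alleles,
        )


@dataclass
class PhenotypeVector:
    """One real-valued record per individual."""

    sample_ids: list
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        if len(self.sample_ids) != self.y.size:
            raise ValueError("sample_ids and y differ in length")
        _check_unique(self.sample_ids, "sample")

    def aligned_to(self, g: GenotypeMatrix) -> "PhenotypeVector":
        """Explicit join: reorder records to match the genotype samples."""
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        try:
            order = [pos[s] for s in g.sample_ids]
        except KeyError as e:
            raise ValueError(f"no phenotype for sample {e.args[0]!r}") from None
        return PhenotypeVector(list(g.sample_ids), self.y[order])


@dataclass
class StandardizedGenotypes:
    """Centred and scaled design matrix for retained (polymorphic) markers.

    ``Z`` has one column per retained marker; ``kept_markers`` indexes those
    columns back into the source :class:`GenotypeMatrix`.  ``diag_zz`` caches
    the column sums of squares ``Z_i' Z_i`` used throughout the estimators.
    """

    Z: np.ndarray
    freqs: np.ndarray
    scale: np.ndarray
    kept_markers: np.ndarray
    marker_ids: list = field(default_factory=list)
    diag_zz: np.ndarray = None

    def __post_init__(self):
        if self.diag_zz is None:
            self.diag_zz = np.einsum("ij,ij->j", self.Z, self.Z)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]


def compute_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per marker, ignoring missing dosages."""
    d = g.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmin(n_obs))
        raise ValueError(f"marker {g.marker_ids[j]!r} has no non-missing dosages")
    return np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs)


def standardize(
    g: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    impute_missing: bool = True,
) -> StandardizedGenotypes:
    """Centre and scale dosages; drop monomorphic markers.

    When ``freqs`` is omitted, frequencies are estimated from ``g`` itself.
    Passing training-set frequencies keeps selection candidates on the same
    centring/scale as the reference population.  Missing dosages are imputed
    to ``2 p_i`` (a zero entry of ``Z``) when ``impute_missing`` is set.
    """
    if freqs is None:
        freqs = compute_allele_frequencies(g)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size != g.m:
        raise ValueError(f"expected {g.m} frequencies, got {freqs.size}")

    kept = np.flatnonzero((freqs > 0.0) & (freqs < 1.0))
    if kept.size == 0:
        raise ValueError("all markers are monomorphic; nothing to standardize")

    p = freqs[kept]
    scale = 1.0 / np.sqrt(2.0 * p * (1.0 - p))
    d = g.dosages[:, kept].astype(float)
    miss = d == MISSING
    if miss.any():
        if impute_missing:
            d[miss] = (2.0 * p)[np.nonzero(miss)[1]]
        else:
            raise ValueError("missing dosages present and impute_missing is off")
    Z = (d - 2.0 * p) * scale
    return StandardizedGenotypes(
        Z=Z,
        freqs=p,
        scale=scale,
        kept_markers=kept,
        marker_ids=[g.marker_ids[j] for j in kept],
    )


# ---------------------------------------------------------------------------
# PLINK 1.9 additive recode (.raw)

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_plink_raw(path):
    """Read a PLINK 1.9 ``--recode A`` file.

    Returns ``(GenotypeMatrix, PhenotypeVector or None)``; the phenotype is
    ``None`` when the PHENOTYPE column is entirely missing (``-9`` or NA).
    Marker columns are named ``<id>_<allele>``; the suffix names the counted
    allele and is stored in ``counted_alleles``.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(_RAW_META)] != _RAW_META:
            raise ValueError(
                f"{path}: line 1: header must start with {' '.join(_RAW_META)}"
            )
        marker_ids, alleles = [], []
        for col in header[len(_RAW_META) :]:
            mid, _, allele = col.rpartition("_")
            if not mid:
                mid, allele = col, ""
            marker_ids.append(mid)
            alleles.append(allele)

        sample_ids, pheno, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            sample_ids.append(parts[1])
            pheno.append(parts[5])
            row = np.empty(len(marker_ids), dtype=np.int8)
            for j, tok in enumerate(parts[len(_RAW_META) :]):
                if tok == "NA":
                    row[j] = MISSING
                elif tok in ("0", "1", "2"):
                    row[j] = int(tok)
                else:
                    raise ValueError(
                        f"{path}: line {lineno}: dosage {tok!r} for marker "
                        f"{marker_ids[j]!r} is not 0/1/2/NA"
                    )
            rows.append(row)

    g = GenotypeMatrix(sample_ids, marker_ids, np.vstack(rows), alleles)
    yvals = np.array(
        [np.nan if v in ("-9", "NA", "nan") else float(v) for v in pheno]
    )
    if np.isnan(yvals).all():
        return g, None
    return g, PhenotypeVector(sample_ids, yvals)


def write_plink_raw(path, g: GenotypeMatrix, phenotype: PhenotypeVector | None = None):
    """Write genotypes (and optional phenotype) in PLINK ``.raw`` layout."""
    alleles = g.counted_alleles or ["A"] * g.m
    y = None
    if phenotype is not None:
        y = phenotype.aligned_to(g).y
    with open(path, "w") as fh:
        cols = [f"{mid}_{a}" for mid, a in zip(g.marker_ids, alleles)]
        fh.write(" ".join(_RAW_META + cols) + "\n")
        for i, sid in enumerate(g.sample_ids):
            ph = "-9" if y is None else repr(float(y[i]))
            toks = [str(sid), str(sid), "0", "0", "0", ph]
            toks += ["NA" if v == MISSING else str(v) for v in g.dosages[i]]
            fh.write(" ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# Plain TSV dosage tables and phenotype files


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a TSV with sample ids in the first column and one marker per column."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    sample_ids = df.iloc[:, 0].tolist()
    marker_ids = list(df.columns[1:])
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    dos = np.where(np.isnan(vals), MISSING, vals)
    if not np.array_equal(dos, np.round(dos)):
        raise ValueError(f"{path}: non-integer dosage values")
    return GenotypeMatrix(sample_ids, marker_ids, dos.astype(np.int8))


def write_dosage_tsv(path, g: GenotypeMatrix):
    dos = g.dosages.astype(object)
    dos[dos == MISSING] = "NA"
    df = pd.DataFrame(dos, columns=g.marker_ids)
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return PhenotypeVector(df.iloc[:, 0].tolist(), df.iloc[:, 1].to_numpy(float))


def write_phenotype_tsv(path, p: PhenotypeVector):
    pd.DataFrame({"sample_id": p.sample_ids, "value": p.y}).to_csv(
        path, sep="\t", index=False
    )
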