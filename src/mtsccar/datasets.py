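"""Loading, alignment, validation and pre-conditioning of the data views.

The model consumes three aligned views per subject: an additively coded
genotype matrix ``X`` (n x p SNPs), one imaging quantitative-trait matrix
per modality ``Y_m`` (n x q ROIs each), and a table of cognitive scores
``Z`` (n x C).  SNPs may additionally carry a group structure (gene or LD
block membership) used by the group-lasso penalty.

Matrices are held as labeled :class:`pandas.DataFrame` objects: the index
is the subject id, columns are feature ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupStructure",
    "StudyDataset",
    "read_labeled_matrix",
    "read_plink_raw",
    "read_groups",
    "residualize_covariates",
    "standardize",
    "assemble_dataset",
]


class DataValidationError(ValueError):
    """Raised when an input file or matrix violates a structural invariant."""


@dataclass(frozen=True)
class GroupStructure:
    """Partition of the ``p`` SNP columns into ``K`` disjoint groups.

    Parameters
    ----------
    labels
        Sequence of length ``p`` giving the group label of each SNP column,
        in column order.  Every SNP belongs to exactly one group; the union
        of groups covers all SNPs by construction.
    """

    labels: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise DataValidationError("group structure must cover at least one SNP")

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def K(self) -> int:
        return len(set(self.labels))

    def indices(self) -> dict[Hashable, np.ndarray]:
        """Mapping group label -> array of SNP column indices (sorted)."""
        out: dict[Hashable, list[int]] = {}
        for i, lab in enumerate(self.labels):
            out.setdefault(lab, []).append(i)
        return {lab: np.asarray(idx, dtype=int) for lab, idx in out.items()}

    @property
    def is_singleton(self) -> bool:
        """tagSNP mode: every SNP is its own group."""
        return self.K == self.p

    @classmethod
    def singletons(cls, snp_ids: Sequence[Hashable]) -> "GroupStructure":
        """tagSNP mode: each SNP forms an individual group."""
        return cls(labels=tuple(snp_ids))

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[Hashable, Hashable], snp_ids: Sequence[Hashable]
    ) -> "GroupStructure":
        """Build from a snp_id -> group_label map; unmapped SNPs become singletons."""
        labels = []
        for sid in snp_ids:
            if sid in mapping:
                labels.append(("G", mapping[sid]))
            else:
                labels.append(("S", sid))
        return cls(labels=tuple(labels))


@dataclass
class StudyDataset:
    """The aligned triple of genotype, imaging and cognitive views.

    Attributes
    ----------
    genotypes
        ``n x p`` genotype matrix (subjects x SNPs).
    modalities
        Ordered list of ``M`` imaging QT matrices, each ``n x q``.  All
        modalities must have the same number of ROIs ``q`` (the cross-task
        L2,1 coupling on the QT weights requires aligned rows).
    cognitive
        ``n x C`` cognitive-score matrix.
    groups
        Optional SNP group structure for the group-lasso penalty.
    class_labels
        Optional per-subject class label (used for stratified CV folds on
        synthetic data).
    """

    genotypes: pd.DataFrame
    modalities: list[pd.DataFrame]
    cognitive: pd.DataFrame
    groups: GroupStructure | None = None
    class_labels: np.ndarray | None = None
    modality_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.modality_names:
            self.modality_names = [f"mod{m + 1}" for m in range(len(self.modalities))]
        self.validate()

    def validate(self) -> None:
        if len(self.modalities) < 1:
            raise DataValidationError("at least one imaging modality is required")
        if self.cognitive.shape[1] < 1:
            raise DataValidationError("at least one cognitive score is required")
        ids = list(self.genotypes.index)
        for m, Y in enumerate(self.modalities):
            if list(Y.index) != ids:
                raise DataValidationError(
                    f"modality {m} subject order differs from the genotype matrix"
                )
        if list(self.cognitive.index) != ids:
            raise DataValidationError(
                "cognitive-score subject order differs from the genotype matrix"
            )
        qs = {Y.shape[1] for Y in self.modalities}
        if len(qs) > 1:
            raise DataValidationError(
                f"all modalities must share the same ROI count, got {sorted(qs)}"
            )
        if self.groups is not None and self.groups.p != self.genotypes.shape[1]:
            raise DataValidationError(
                f"group structure covers {self.groups.p} SNPs but the genotype "
                f"matrix has {self.genotypes.shape[1]}"
            )

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def p(self) -> int:
        return self.genotypes.shape[1]

    @property
    def q(self) -> int:
        return self.modalities[0].shape[1]

    @property
    def M(self) -> int:
        return len(self.modalities)

    @property
    def C(self) -> int:
        return self.cognitive.shape[1]

    @property
    def subject_ids(self) -> list:
        return list(self.genotypes.index)

    def to_arrays(self) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
        """Return (X, [Y_m], Z) as float arrays."""
        X = self.genotypes.to_numpy(dtype=float)
        Ys = [Y.to_numpy(dtype=float) for Y in self.modalities]
        Z = self.cognitive.to_numpy(dtype=float)
        return X, Ys, Z

    def subset(self, rows: np.ndarray) -> "StudyDataset":
        """Row-subset (e.g. a CV fold) preserving labels and groups."""
        return StudyDataset(
            genotypes=self.genotypes.iloc[rows],
            modalities=[Y.iloc[rows] for Y in self.modalities],
            cognitive=self.cognitive.iloc[rows],
            groups=self.groups,
            class_labels=None if self.class_labels is None else self.class_labels[rows],
            modality_names=list(self.modality_names),
        )


def _check_labels(df: pd.DataFrame, path: Path) -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataValidationError(f"{path}: duplicate subject id(s): {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise DataValidationError(f"{path}: duplicate feature id(s): {dup}")


def read_labeled_matrix(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a labeled numeric matrix from a delimited text file.

    The first row is the feature header, the first column holds subject
    ids.  Missing cells (empty or ``NA``/``NaN``) are kept as NaN and must
    be handled downstream; any other non-numeric cell is a hard error that
    names the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise DataValidationError(f"{path}: empty matrix")
    _check_labels(raw, path)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    bad &= ~raw.isin(["NA", "NaN", "nan"])
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"{path}: non-numeric value {raw.iloc[r, c]!r} at subject "
            f"{raw.index[r]!r}, feature {raw.columns[c]!r}"
        )
    return numeric.astype(float)


def read_plink_raw(path: str | Path) -> pd.DataFrame:
    """Read a PLINK ``.raw`` additively recoded genotype file.

    Returns a subjects x SNPs matrix of minor-allele counts {0, 1, 2};
    missing genotypes become NaN.  Column ids are SNP names with the
    trailing ``_<allele>`` suffix stripped; the row index is the IID.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != meta:
        raise DataValidationError(
            f"{path}: malformed .raw header, expected leading columns {meta}"
        )
    geno = df.set_index("IID").drop(columns=[c for c in meta if c != "IID"])
    geno.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
    _check_labels(geno, path)
    values = geno.apply(pd.to_numeric, errors="coerce")
    not_na = geno.notna() & ~geno.isin(["NA", "NaN", "nan"])
    invalid = not_na & ~values.isin([0.0, 1.0, 2.0])
    if invalid.to_numpy().any():
        r, c = np.argwhere(invalid.to_numpy())[0]
        raise DataValidationError(
            f"{path}: genotype {geno.iloc[r, c]!r} outside {{0,1,2,NA}} at "
            f"subject {geno.index[r]!r}, SNP {geno.columns[c]!r}"
        )
    return values.astype(float)


def read_groups(path: str | Path, snp_ids: Sequence[str]) -> GroupStructure:
    """Read a two-column (snp_id, group_label) TSV into a group structure.

    SNPs absent from the file are assigned their own singleton group.  An
    empty file therefore yields tagSNP mode (K = p).  A SNP listed twice
    with conflicting labels is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataValidationError(
                    f"{path}:{line_no}: expected two tab-separated columns"
                )
            sid, lab = parts[0].strip(), parts[1].strip()
            if sid in mapping and mapping[sid] != lab:
                raise DataValidationError(
                    f"{path}: SNP {sid!r} mapped to conflicting groups "
                    f"{mapping[sid]!r} and {lab!r}"
                )
            mapping[sid] = lab
    return GroupStructure.from_mapping(mapping, snp_ids)


def residualize_covariates(
    matrix: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Regress out covariates (plus an intercept) from every column.

    Used to adjust imaging QTs for nuisance variables such as age, sex and
    education.  Each column is replaced by its least-squares residual on
    ``[1 | covariates]``; residuals are mean-zero and orthogonal to every
    covariate column.
    """
    if list(matrix.index) != list(covariates.index):
        raise DataValidationError("matrix and covariates must share subject order")
    n = matrix.shape[0]
    design = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise DataValidationError(
            "covariate design matrix is rank deficient after adding an "
            "intercept; remove collinear or constant covariate columns"
        )
    Y = matrix.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization to mean 0 and unit sample sd (ddof=1)."""
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DataValidationError(
            f"zero-variance column(s): {[matrix.columns[i] for i in zero[:5]]}"
        )
    out = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _center(matrix: pd.DataFrame) -> pd.DataFrame:
    values = matrix.to_numpy(dtype=float)
    return pd.DataFrame(
        values - values.mean(axis=0), index=matrix.index, columns=matrix.columns
    )


def assemble_dataset(
    genotypes: pd.DataFrame,
    modalities: Sequence[pd.DataFrame],
    cognitive: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    groups: GroupStructure | None = None,
    *,
    scale: bool = True,
    adjust_cognitive: bool = False,
    impute_missing: bool = False,
    modality_names: Sequence[str] | None = None,
) -> StudyDataset:
    """Align views by subject id and apply pre-conditioning.

    Subjects are intersected across all views (a warning lists any dropped
    ids) and ordered as in the genotype matrix.  Covariates, when given,
    are residualized out of the imaging QTs (and, optionally, the
    cognitive scores).  With ``scale=True`` (the default) genotype and
    imaging columns are standardized and cognitive scores are
    mean-centered — the unit-variance projection constraints of the solver
    presume comparable column scales.

    Missing genotypes are a hard error unless ``impute_missing=True``, in
    which case they are replaced by the column mean before scaling.
    """
    common = set(genotypes.index)
    for Y in modalities:
        common &= set(Y.index)
    common &= set(cognitive.index)
    if covariates is not None:
        common &= set(covariates.index)
    order = [sid for sid in genotypes.index if sid in common]
    if not order:
        raise DataValidationError("no subjects shared across all views")
    seen = set(genotypes.index) | set(cognitive.index)
    for Y in modalities:
        seen |= set(Y.index)
    dropped = sorted(seen - common)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} subject(s) absent from some view: "
            f"{dropped[:10]}",
            stacklevel=2,
        )
    X = genotypes.loc[order]
    Ys = [Y.loc[order] for Y in modalities]
    Z = cognitive.loc[order]

    if X.isna().to_numpy().any():
        if not impute_missing:
            raise DataValidationError(
                "genotype matrix contains missing values; pass "
                "impute_missing=True for column-mean imputation"
            )
        X = X.fillna(X.mean(axis=0))
    for m, Y in enumerate(Ys):
        if Y.isna().to_numpy().any():
            raise DataValidationError(f"modality {m} contains missing values")
    if Z.isna().to_numpy().any():
        raise DataValidationError("cognitive scores contain missing values")

    if covariates is not None:
        cov = covariates.loc[order]
        Ys = [residualize_covariates(Y, cov) for Y in Ys]
        if adjust_cognitive:
            Z = residualize_covariates(Z, cov)

    if scale:
        X = standardize(X)
        Ys = [standardize(Y) for Y in Ys]
        Z = _center(Z)

    return StudyDataset(
        genotypes=X,
        modalities=list(Ys),
        cognitive=Z,
        groups=groups,
        modality_names=list(modality_names) if modality_names else [],
    )
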