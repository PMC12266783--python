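"""On-disk formats and shared genomic-coordinate conventions.

All internal coordinates are 0-based half-open. Fields documented as
1-based (manifest ``pos``, ``GeneModel.tss``, ``MethylationPeak.pos``)
are converted at the boundary: BED is ingested as 0-based half-open,
GTF and the probe manifest as 1-based, and every writer emits the
dialect its format prescribes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("methregen")

FEATURE_CLASSES = (
    "promoter",
    "exon",
    "intron",
    "five_prime_utr",
    "three_prime_utr",
    "intergenic_downstream",
    "intergenic",
)

AGE_GROUPS = ("young", "old")
TREATMENTS = ("vehicle", "senolytic")
LIMBS = ("PBS", "BaCl2")

#: study arm -> (age_group, treatment)
ARMS = {
    "YV": ("young", "vehicle"),
    "OV": ("old", "vehicle"),
    "OS": ("old", "senolytic"),
}


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates its declared contract."""


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    Missing values are carried as NaN in :attr:`values` and exposed through
    :attr:`missing_mask`; they are never imputed here (gold-median
    imputation is clock-specific).
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe_id(s): {dups[:5]}")
        if values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in beta matrix")
        arr = values.to_numpy(dtype=float)
        bad = (~np.isnan(arr)) & ((arr < 0.0) | (arr > 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]} outside [0, 1] at probe "
                f"{values.index[i]!r}, sample {values.columns[j]!r}"
            )
        self.values = values.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a TSV/CSV beta matrix (first column probe_id, header sample ids)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    beta.values.to_csv(path, sep=sep, index_label="probe_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "gene_id", "feature_class", "tss_distance"]


def validate_manifest(df: pd.DataFrame, promoter_window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Validate a probe manifest table (``pos`` is 1-based).

    ``promoter_window`` is the (upstream, downstream) signed TSS-distance
    window; when given, promoter probes must fall inside it.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing column(s): {missing}")
    if df["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe_id in manifest")
    if (df["pos"] < 1).any():
        raise ValidationError("manifest pos must be >= 1 (1-based)")
    bad_fc = set(df["feature_class"]) - set(FEATURE_CLASSES)
    if bad_fc:
        raise ValidationError(f"unknown feature_class values: {sorted(bad_fc)}")
    prom = df[df["feature_class"] == "promoter"]
    if prom["gene_id"].isna().any():
        raise ValidationError("promoter probes must carry a gene_id")
    if promoter_window is not None:
        lo, hi = promoter_window
        d = prom["tss_distance"]
        if ((d < lo) | (d > hi)).any():
            raise ValidationError(
                f"promoter probe tss_distance outside window [{lo}, {hi}]"
            )
    return df.reset_index(drop=True)


def read_manifest(path: str | Path, promoter_window: tuple[int, int] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "chrom": str})
    return validate_manifest(df, promoter_window)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "animal_id", "age_group", "treatment", "limb", "batch"]


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet missing column(s): {missing}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    for col, allowed in (("age_group", AGE_GROUPS), ("treatment", TREATMENTS), ("limb", LIMBS)):
        bad = set(df[col]) - set(allowed)
        if bad:
            raise ValidationError(f"unknown {col} values: {sorted(bad)}")
    per_limb = df.groupby(["animal_id", "limb"]).size()
    if (per_limb > 1).any():
        offending = per_limb[per_limb > 1].index.tolist()
        raise ValidationError(f"animal with >1 sample per limb: {offending}")
    return df.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return validate_sample_sheet(df)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def arm_samples(sheet: pd.DataFrame, arm: str) -> pd.DataFrame:
    """Subset the sheet to one study arm (``YV``/``OV``/``OS``)."""
    try:
        age_group, treatment = ARMS[arm]
    except KeyError:
        raise ValidationError(f"unknown arm {arm!r}; expected one of {sorted(ARMS)}")
    sub = sheet[(sheet["age_group"] == age_group) & (sheet["treatment"] == treatment)]
    return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware TSS.

    ``tss`` is 1-based; ``start``/``end`` are the internal 0-based
    half-open span. On the + strand the TSS is the span's first base, on
    the - strand its last.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        expected = self.start + 1 if self.strand == "+" else self.end
        if self.tss != expected:
            raise ValidationError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"{self.strand}-strand span [{self.start}, {self.end})"
            )


def _genes_from_ranges(df: pd.DataFrame) -> list[GeneModel]:
    genes = []
    for row in df.itertuples(index=False):
        strand = str(row.Strand)
        if strand not in ("+", "-"):
            raise ValidationError(
                f"gene {row.gene_id}: missing/invalid strand {strand!r} (TSS undefined)"
            )
        start, end = int(row.Start), int(row.End)
        tss = start + 1 if strand == "+" else end
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                symbol=str(getattr(row, "symbol", row.gene_id)),
                chrom=str(row.Chromosome),
                strand=strand,
                tss=tss,
                start=start,
                end=end,
            )
        )
    return genes


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (0-based half-open) or GTF (1-based closed).

    Both dialects are normalized to the same internal representation, so a
    gene described in either format yields an identical :class:`GeneModel`.
    """
    import pyranges as pr

    p = str(path)
    if p.endswith((".gtf", ".gff", ".gtf.gz")):
        gr = pr.read_gtf(p)
        df = gr.df
        df = df[df["Feature"].isin(["gene", "transcript"])] if "Feature" in df else df
        if "gene_id" not in df.columns:
            raise ValidationError("GTF lacks gene_id attribute")
        if "gene_name" in df.columns:
            df = df.rename(columns={"gene_name": "symbol"})
        df = df.drop_duplicates(subset="gene_id")
    else:
        gr = pr.read_bed(p)
        df = gr.df
        if "Name" not in df.columns or "Strand" not in df.columns:
            raise ValidationError("BED gene models need >=6 columns (name, strand)")
        df = df.rename(columns={"Name": "gene_id"})
        df["symbol"] = df["gene_id"]
    return _genes_from_ranges(df)


def write_gene_models_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene_id", "log2_fold_change", "p", "adj_p"]


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"DE table missing column(s): {missing}")
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in DE table")
    for col in ("p", "adj_p"):
        v = df[col].to_numpy(dtype=float)
        ok = np.isnan(v) | ((v >= 0) & (v <= 1))
        if not ok.all():
            raise ValidationError(f"DE {col} outside [0, 1]")
    return df.reset_index(drop=True)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    return validate_de_table(df)


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Methylation peaks (BED)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class MethylationPeak:
    """A significant DM CpG recast as a single-bp genomic feature.

    ``pos`` is 1-based; the BED serialization converts to 0-based
    half-open single-base intervals.
    """

    chrom: str
    pos: int
    probe_id: str
    direction: str  # "hypo" | "hyper"

    def __post_init__(self):
        if self.direction not in ("hypo", "hyper"):
            raise ValidationError(f"peak {self.probe_id}: bad direction {self.direction!r}")
        if self.pos < 1:
            raise ValidationError(f"peak {self.probe_id}: pos must be 1-based >= 1")


_PEAKS_HEADER = (
    "# methylation peaks: single-bp BED intervals derived from significant DM CpGs\n"
    "# columns: chrom, start (0-based), end, probe_id, direction sign (+1 hyper / -1 hypo), strand\n"
)


def write_peaks_bed(peaks: Sequence[MethylationPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_PEAKS_HEADER)
        for pk in peaks:
            score = 1 if pk.direction == "hyper" else -1
            fh.write(f"{pk.chrom}\t{pk.pos - 1}\t{pk.pos}\t{pk.probe_id}\t{score}\t.\n")


def read_peaks_bed(path: str | Path) -> list[MethylationPeak]:
    peaks: list[MethylationPeak] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score = line.split("\t")[:5]
            if int(end) - int(start) != 1:
                raise ValidationError(f"peak {name}: not a single-bp interval")
            peaks.append(
                MethylationPeak(
                    chrom=chrom,
                    pos=int(start) + 1,
                    probe_id=name,
                    direction="hyper" if int(score) > 0 else "hypo",
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# Logging / misc plumbing
# ---------------------------------------------------------------------------


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def dataclass_to_dict(obj) -> dict:
    return dataclasses.asdict(obj)
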