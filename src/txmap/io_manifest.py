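"""Study-design and input parsing.

The meta-analysis starts from four tab-delimited inputs:

* a **sample manifest** describing every microarray sample: which series
  (dataset) it belongs to, which platform measured it, donor sex, the
  comparison pool it is assigned to, and whether its values are stored on a
  linear or log2 scale;
* one **platform annotation** table per platform, mapping probe identifiers
  to gene symbols;
* a **gene locus map** placing each gene symbol on a chromosome with 1-based
  inclusive start/end coordinates;
* per-dataset **expression matrices** (probes x samples).

Donor-level inclusion rules (adult donors, non-obese, early culture passage)
are expressed as :class:`InclusionCriteria` and applied with
:func:`apply_inclusion_filters`.  A record that does not state a criterion
field passes that criterion: public study metadata frequently reports ages
as "Adult" or a range, and such samples are retained.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SEXES = ("M", "F")
POOLS = ("A", "B", "C", "D")
SCALES = ("linear", "log2")

#: age as a point value, an (low, high) interval, the marker "adult", or None
AgeValue = Union[float, tuple, str, None]

_POOL_RE = re.compile(r"^([A-D])(?:\s*\(([CD])\))?$")
_RANGE_RE = re.compile(
    r"^\(?\s*(\d+(?:\.\d+)?)\s*[–—-]\s*(\d+(?:\.\d+)?)\s*\)?$"
)
_MISSING = {"", "na", "n/a", "none", "-", "nan"}


def parse_age(text: str) -> AgeValue:
    """Parse an age cell: number, "mean ± sd", "(low–high)", "Adult" or missing."""
    t = str(text).strip()
    if t.lower() in _MISSING:
        return None
    if t.lower() == "adult":
        return "adult"
    if "±" in t:  # "40.2 ± 14.2" -> mean
        return float(t.split("±")[0].strip())
    m = _RANGE_RE.match(t)
    if m:
        return (float(m.group(1)), float(m.group(2)))
    try:
        return float(t)
    except ValueError as exc:
        raise FormatError(f"unparseable age value {text!r}") from exc


def _parse_optional_float(text: str, what: str) -> float | None:
    t = str(text).strip()
    if t.lower() in _MISSING:
        return None
    try:
        return float(t)
    except ValueError as exc:
        raise FormatError(f"unparseable {what} value {text!r}") from exc


def _parse_optional_int(text: str, what: str) -> int | None:
    v = _parse_optional_float(text, what)
    return None if v is None else int(v)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    dataset_id: str
    platform_id: str
    sex: str
    pool: str
    scale: str
    subpool: str | None = None  # pool-B samples may carry C or D
    age_years: AgeValue = None
    passage: int | None = None
    bmi: float | None = None

    def in_pool(self, pool_id: str) -> bool:
        """Membership test honouring subpools (C/D are subsets of B)."""
        return self.pool == pool_id or self.subpool == pool_id


@dataclass
class SampleManifest:
    """Validated study design: one record per sample, file order preserved."""

    records: list[SampleRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def samples_in_pool(self, pool_id: str) -> list[SampleRecord]:
        return [r for r in self.records if r.in_pool(pool_id)]

    def pool_counts(self) -> dict[str, int]:
        return {p: len(self.samples_in_pool(p)) for p in POOLS}

    @property
    def dataset_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.dataset_id, None)
        return list(seen)

    @property
    def platform_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.platform_id, None)
        return list(seen)

    def scale_of(self, sample_id: str) -> str:
        for r in self.records:
            if r.sample_id == sample_id:
                return r.scale
        raise KeyError(sample_id)


@dataclass(frozen=True)
class InclusionCriteria:
    """Donor-level inclusion rules; all bounds strict, missing fields pass."""

    min_age_years: float = 18.0
    max_bmi: float = 30.0
    allowed_passages: tuple[int, int] = (1, 4)
    require_sex: bool = True

    def admits(self, rec: SampleRecord) -> bool:
        age = rec.age_years
        if isinstance(age, tuple):
            # interval-valued ages are imprecise metadata of declared-adult
            # donors: the lower bound only needs to reach the threshold
            if not age[0] >= self.min_age_years:
                return False
        elif isinstance(age, float):
            if not age > self.min_age_years:
                return False
        # None and the "adult" marker pass the age criterion
        if rec.bmi is not None and not rec.bmi < self.max_bmi:
            return False
        if rec.passage is not None:
            lo, hi = self.allowed_passages
            if not lo <= rec.passage <= hi:
                return False
        if self.require_sex and rec.sex not in SEXES:
            return False
        return True


REQUIRED_COLUMNS = ("sample_id", "dataset_id", "platform_id", "sex", "pool", "scale")


def parse_manifest(path: str | Path) -> SampleManifest:
    """Read and validate a tab-delimited sample manifest.

    Raises :class:`FormatError` on missing required columns and
    :class:`ValidationError` on duplicate sample ids or pool/sex
    inconsistencies (pool A must be male, pool B female).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"manifest is missing required column '{col}'")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in seen:
            raise ValidationError(f"duplicate sample_id '{sid}'")
        seen.add(sid)
        sex = row["sex"].strip()
        if sex not in SEXES:
            raise ValidationError(f"sample '{sid}': unknown sex {sex!r}")
        m = _POOL_RE.match(row["pool"].strip())
        if not m:
            raise ValidationError(f"sample '{sid}': unparseable pool {row['pool']!r}")
        pool, subpool = m.group(1), m.group(2)
        if pool == "A" and sex != "M":
            raise ValidationError(f"sample '{sid}': pool A requires sex M")
        if pool == "B" and sex != "F":
            raise ValidationError(f"sample '{sid}': pool B requires sex F")
        if subpool and pool != "B":
            raise ValidationError(f"sample '{sid}': subpool only allowed within pool B")
        scale = row["scale"].strip()
        if scale not in SCALES:
            raise ValidationError(f"sample '{sid}': unknown scale {scale!r}")
        records.append(
            SampleRecord(
                sample_id=sid,
                dataset_id=row["dataset_id"].strip(),
                platform_id=row["platform_id"].strip(),
                sex=sex,
                pool=pool,
                subpool=subpool,
                scale=scale,
                age_years=parse_age(row["age"]) if "age" in df.columns else None,
                passage=_parse_optional_int(row["passage"], "passage")
                if "passage" in df.columns
                else None,
                bmi=_parse_optional_float(row["bmi"], "bmi")
                if "bmi" in df.columns
                else None,
            )
        )
    return SampleManifest(records)


def _format_age(age: AgeValue) -> str:
    if age is None:
        return "N/A"
    if age == "adult":
        return "Adult"
    if isinstance(age, tuple):
        lo, hi = age
        return f"({_fmt_num(lo)}–{_fmt_num(hi)})"
    return _fmt_num(age)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    """Serialize a manifest so that ``parse_manifest`` round-trips it."""
    rows = []
    for r in manifest:
        pool = r.pool if r.subpool is None else f"{r.pool} ({r.subpool})"
        rows.append(
            {
                "sample_id": r.sample_id,
                "dataset_id": r.dataset_id,
                "platform_id": r.platform_id,
                "sex": r.sex,
                "pool": pool,
                "age": _format_age(r.age_years),
                "scale": r.scale,
                "passage": "" if r.passage is None else str(r.passage),
                "bmi": "" if r.bmi is None else _fmt_num(r.bmi),
            }
        )
    pd.DataFrame(rows, columns=["sample_id", "dataset_id", "platform_id", "sex",
                                "pool", "age", "scale", "passage", "bmi"]).to_csv(
        path, sep="\t", index=False
    )


def apply_inclusion_filters(
    manifest: SampleManifest, criteria: InclusionCriteria | None = None
) -> SampleManifest:
    """Return the sub-manifest of records passing all inclusion criteria."""
    criteria = criteria or InclusionCriteria()
    kept = [r for r in manifest if criteria.admits(r)]
    if len(kept) < len(manifest):
        logger.info("inclusion filters removed %d of %d samples",
                    len(manifest) - len(kept), len(manifest))
    return SampleManifest(kept)


# ---------------------------------------------------------------------------
# platform annotation


@dataclass
class PlatformAnnotation:
    platform_id: str
    probe_to_gene: dict[str, str]

    @property
    def gene_symbols(self) -> set[str]:
        return set(self.probe_to_gene.values())

    def __len__(self) -> int:
        return len(self.probe_to_gene)


def load_platform(path: str | Path, platform_id: str | None = None) -> PlatformAnnotation:
    """Load a two-column probe→gene-symbol table.

    Probes with a blank symbol are omitted.  Duplicate probe rows with the
    same symbol are deduplicated; conflicting symbols raise.
    """
    path = Path(path)
    platform_id = platform_id or path.stem
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     header=0, names=["probe_id", "gene_symbol"])
    mapping: dict[str, str] = {}
    total = 0
    for probe, symbol in zip(df["probe_id"], df["gene_symbol"]):
        probe, symbol = probe.strip(), symbol.strip()
        total += 1
        if not symbol:
            continue
        if probe in mapping and mapping[probe] != symbol:
            raise ValidationError(
                f"platform '{platform_id}': probe '{probe}' maps to both "
                f"'{mapping[probe]}' and '{symbol}'"
            )
        mapping[probe] = symbol
    if not mapping:
        logger.warning("platform '%s': no mapped probes", platform_id)
    logger.info("platform '%s': %d probes, %d mapped", platform_id, total, len(mapping))
    return PlatformAnnotation(platform_id, mapping)


# ---------------------------------------------------------------------------
# gene loci


@dataclass(frozen=True)
class GeneLocus:
    chromosome: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


@dataclass
class GeneLocusMap:
    """One genomic locus per gene symbol, plus chromosome lengths.

    Coordinates are 1-based inclusive throughout the package.
    """

    loci: dict[str, GeneLocus]
    chromosome_lengths: dict[str, int]

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.loci

    def __getitem__(self, symbol: str) -> GeneLocus:
        return self.loci[symbol]

    def genes_on(self, chromosome: str) -> list[str]:
        """Symbols on one chromosome ordered by start coordinate."""
        syms = [s for s, l in self.loci.items() if l.chromosome == chromosome]
        return sorted(syms, key=lambda s: (self.loci[s].start, s))

    def validate(self) -> None:
        for sym, loc in self.loci.items():
            if loc.start < 1 or loc.start > loc.end:
                raise ValidationError(f"gene '{sym}': invalid interval "
                                      f"{loc.start}-{loc.end}")
            length = self.chromosome_lengths.get(loc.chromosome)
            if length is not None and loc.end > length:
                raise ValidationError(
                    f"gene '{sym}': end {loc.end} exceeds length of "
                    f"{loc.chromosome} ({length})"
                )


def load_gene_loci(
    path: str | Path,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> GeneLocusMap:
    """Load a gene locus table (gene, chromosome, start, end; 1-based inclusive).

    When ``chromosome_lengths`` is not supplied, each chromosome's length is
    taken as the maximum gene end observed on it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     header=0, names=["gene", "chromosome", "start", "end"])
    loci: dict[str, GeneLocus] = {}
    for _, row in df.iterrows():
        sym = row["gene"].strip()
        try:
            start, end = int(row["start"].replace(",", "")), int(row["end"].replace(",", ""))
        except ValueError as exc:
            raise FormatError(f"gene '{sym}': non-integer coordinates") from exc
        loc = GeneLocus(row["chromosome"].strip(), start, end)
        if start < 1 or start > end:
            raise ValidationError(f"gene '{sym}': invalid interval {start}-{end}")
        if sym in loci and loci[sym] != loc:
            raise ValidationError(f"gene '{sym}' has more than one locus")
        loci[sym] = loc
    if chromosome_lengths is None:
        chromosome_lengths = {}
        for loc in loci.values():
            cur = chromosome_lengths.get(loc.chromosome, 0)
            chromosome_lengths[loc.chromosome] = max(cur, loc.end)
    lmap = GeneLocusMap(loci, dict(chromosome_lengths))
    lmap.validate()
    return lmap


def write_gene_loci(lmap: GeneLocusMap, path: str | Path) -> None:
    rows = [
        {"gene": s, "chromosome": l.chromosome, "start": l.start, "end": l.end}
        for s, l in lmap.loci.items()
    ]
    pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ProbeMatrix:
    """Probe-level expression for one dataset.

    ``data`` is probes x samples with NaN for absent cells (an absent cell is
    "no data point", never zero).  ``scales`` declares the encoding of each
    sample column ("linear" or "log2").
    """

    dataset_id: str
    platform_id: str
    data: pd.DataFrame
    scales: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def n_present(self) -> int:
        return int(self.data.notna().to_numpy().sum())


def load_expression(
    path: str | Path,
    dataset_id: str,
    platform_id: str,
    scales: Mapping[str, str],
) -> ProbeMatrix:
    """Load a probe x sample expression TSV (header row of sample ids).

    Empty cells become NaN ("absent"); any other non-numeric cell raises a
    :class:`FormatError` naming the offending probe row and sample column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    values = df.apply(lambda col: pd.to_numeric(col.str.strip().replace("", np.nan),
                                                errors="coerce"))
    bad = values.isna() & (df.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"dataset '{dataset_id}': non-numeric value {df.iat[r, c]!r} at "
            f"probe '{df.index[r]}', sample '{df.columns[c]}'"
        )
    return ProbeMatrix(dataset_id, platform_id, values.astype(float),
                       {s: scales[s] for s in df.columns})
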