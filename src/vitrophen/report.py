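"""Batch processing of image directories into trait and summary tables.

Each image yields one :class:`TraitRecord`; failures of individual traits
are recorded as missing values with a warning string, never aborting the
batch. Summaries are grouped by (treatment, day) with mean, standard error
(sample SD/√n) and a normal-approximation 95% CI half-width (1.96·SE).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from vitrophen import morpho, verdancy
from vitrophen.errors import UndefinedTraitError, VitrophenError
from vitrophen.segment import SegmentationConfig, segment_plant

logger = logging.getLogger("vitrophen")

TRAIT_COLUMNS = (
    "area",
    "hull_area",
    "perimeter",
    "solidity",
    "greenness",
    "area_above",
    "area_below",
)

CSV_COLUMNS = (
    "plant_id",
    "treatment",
    "day",
    "image",
    "area",
    "hull_area",
    "perimeter",
    "solidity",
    "greenness",
    "n_qualifying",
    "area_above",
    "area_below",
    "warnings",
)

#: default filename metadata pattern: <treatment>_<plantid>_day<D>
FILENAME_PATTERN = re.compile(
    r"^(?P<treatment>.+)_(?P<plant_id>[^_]+)_day(?P<day>\d+)$"
)


@dataclass
class TraitRecord:
    plant_id: str
    treatment: str
    day: int
    image: str
    area: Optional[int] = None
    hull_area: Optional[int] = None
    perimeter: Optional[float] = None
    solidity: Optional[float] = None
    greenness: Optional[float] = None
    n_qualifying: Optional[int] = None
    area_above: Optional[int] = None
    area_below: Optional[int] = None
    warnings: List[str] = field(default_factory=list)

    def as_row(self) -> Dict[str, object]:
        row = {c: getattr(self, c) for c in CSV_COLUMNS if c != "warnings"}
        if row["greenness"] is not None:
            row["greenness"] = round(row["greenness"], 1)
        if row["solidity"] is not None:
            row["solidity"] = round(row["solidity"], 6)
        if row["perimeter"] is not None:
            row["perimeter"] = round(row["perimeter"], 2)
        row["warnings"] = ";".join(self.warnings)
        return row


def metadata_from_filename(path: str | Path) -> Dict[str, object]:
    """Parse ``<treatment>_<plantid>_day<D>`` metadata from an image filename."""
    stem = Path(path).stem
    m = FILENAME_PATTERN.match(stem)
    if not m:
        raise VitrophenError(
            f"cannot parse metadata from filename {stem!r}; "
            "expected <treatment>_<plantid>_day<D>"
        )
    return {
        "treatment": m.group("treatment"),
        "plant_id": m.group("plant_id"),
        "day": int(m.group("day")),
    }


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def process_image(
    path: str | Path,
    metadata: Optional[Dict[str, object]] = None,
    cfg: SegmentationConfig | None = None,
    image: Optional[np.ndarray] = None,
) -> TraitRecord:
    """Segment one image and fill a full trait record.

    ``metadata`` may carry treatment/plant_id/day plus a per-image
    ``medium_row`` override; missing metadata is parsed from the filename.
    ``image`` may supply the pixel data directly (e.g. in-memory scenes).
    """
    if cfg is None:
        cfg = SegmentationConfig()
    if metadata is None:
        metadata = metadata_from_filename(path)
    medium_row = metadata.get("medium_row", cfg.medium_row)
    if medium_row is not None and not pd.isna(medium_row):
        medium_row = int(medium_row)
    else:
        medium_row = None

    record = TraitRecord(
        plant_id=str(metadata["plant_id"]),
        treatment=str(metadata["treatment"]),
        day=int(metadata["day"]),
        image=str(path),
    )

    if image is None:
        image = load_image(path)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        mask, masked = segment_plant(image, cfg)
    for w in caught:
        record.warnings.append(str(w.message))

    record.area = morpho.pixel_area(mask)
    try:
        traits = morpho.compute_traits(mask, medium_row=medium_row)
        record.hull_area = traits.hull_area
        record.perimeter = traits.perimeter
        record.solidity = traits.solidity
        record.area_above = traits.area_above
        record.area_below = traits.area_below
    except UndefinedTraitError as exc:
        record.warnings.append(f"shape traits missing: {exc}")
    if medium_row is None:
        record.warnings.append("no medium_row configured; above/below split skipped")

    try:
        g = verdancy.greenness_index(masked, mask)
        record.greenness = g.index
        record.n_qualifying = g.n_qualifying
    except UndefinedTraitError as exc:
        record.n_qualifying = exc.n_qualifying or 0
        record.warnings.append(f"greenness missing: {exc}")

    return record


def records_to_frame(records: Sequence[TraitRecord]) -> pd.DataFrame:
    frame = pd.DataFrame.from_records([r.as_row() for r in records])
    return frame.reindex(columns=list(CSV_COLUMNS))


def summarize(records: Sequence[TraitRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-(treatment, day) summary: n, and mean/SE/1.96·SE per trait.

    SE is the sample standard deviation over √n of the non-missing values;
    a single-value group reports SE = 0 and is flagged in ``flags``.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(records)
    if frame.empty:
        cols = ["treatment", "day", "n", "flags"]
        for t in TRAIT_COLUMNS:
            cols += [f"{t}_n", f"{t}_mean", f"{t}_se", f"{t}_ci95"]
        return pd.DataFrame(columns=cols)

    rows = []
    for (treatment, day), group in frame.groupby(["treatment", "day"], sort=True):
        row: Dict[str, object] = {
            "treatment": treatment,
            "day": day,
            "n": len(group),
        }
        flags = []
        for trait in TRAIT_COLUMNS:
            values = pd.to_numeric(group[trait], errors="coerce").dropna()
            n = len(values)
            row[f"{trait}_n"] = n
            if n == 0:
                row[f"{trait}_mean"] = np.nan
                row[f"{trait}_se"] = np.nan
                row[f"{trait}_ci95"] = np.nan
                continue
            mean = float(values.mean())
            se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            if n == 1:
                flags.append(f"{trait}:n=1")
            row[f"{trait}_mean"] = mean
            row[f"{trait}_se"] = se
            row[f"{trait}_ci95"] = 1.96 * se
        row["flags"] = ";".join(flags)
        rows.append(row)
    out = pd.DataFrame(rows)
    lead = ["treatment", "day", "n"]
    tail = [c for c in out.columns if c not in lead + ["flags"]] + ["flags"]
    return out[lead + tail]


def _manifest_lookup(manifest: Optional[pd.DataFrame]) -> Dict[str, Dict[str, object]]:
    if manifest is None:
        return {}
    table = {}
    for _, row in manifest.iterrows():
        table[str(row["image"])] = row.to_dict()
    return table


def run_batch(
    input_dir: str | Path,
    manifest: Optional[str | Path | pd.DataFrame] = None,
    cfg: SegmentationConfig | None = None,
    out_dir: str | Path = "out",
    debug_images: bool = False,
) -> pd.DataFrame:
    """Process every PNG/JPEG in ``input_dir``; write traits.csv and summary.csv.

    Images are processed in sorted filename order so outputs are
    deterministic. Per-file failures are logged and skipped.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise VitrophenError(f"input directory {input_dir} does not exist")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if manifest is not None and not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    lookup = _manifest_lookup(manifest)

    paths = sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    records: List[TraitRecord] = []
    statuses = []
    for path in paths:
        meta = lookup.get(path.name)
        try:
            record = process_image(path, metadata=meta, cfg=cfg)
        except Exception as exc:  # fault isolation: one bad file never stops the batch
            logger.error("failed to process %s: %s", path.name, exc)
            statuses.append(f"{path.name}\tERROR\t{exc}")
            continue
        record.image = path.name
        records.append(record)
        statuses.append(f"{path.name}\tOK\t{';'.join(record.warnings)}")
        if debug_images:
            _write_debug(path, record, cfg, out_dir)

    missing = sorted(set(lookup) - {p.name for p in paths})
    for name in missing:
        statuses.append(f"{name}\tMISSING\tlisted in manifest but not found")

    traits = records_to_frame(records)
    traits.to_csv(out_dir / "traits.csv", index=False)
    summary = summarize(traits) if len(traits) else summarize([])
    summary.to_csv(out_dir / "summary.csv", index=False)

    log_lines = [f"# vitrophen run: {len(records)}/{len(paths)} images processed",
                 f"# config: {cfg}"] + statuses
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return traits


def _write_debug(path: Path, record: TraitRecord, cfg: SegmentationConfig, out_dir: Path) -> None:
    from vitrophen.segment import segment_plant as _seg

    image = load_image(path)
    mask, masked = _seg(image, cfg)
    debug_dir = out_dir / "debug"
    debug_dir.mkdir(exist_ok=True)
    Image.fromarray((mask * np.uint8(255))).save(debug_dir / f"{path.stem}_mask.png")
    Image.fromarray(masked).save(debug_dir / f"{path.stem}_masked.png")
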