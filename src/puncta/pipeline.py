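"""End-to-end quantification pipeline and its configuration.

Per field: project → exclude → segment nuclei → detect spots → calibrate
unit copy intensity → decompose clusters into copies → assign spots to
cells → classify lineage → bin test probes → H-score.  Per sample, cells
are pooled across that sample's fields before scoring (the H-score is
defined over the entire area analysed, so pooling — not averaging of
field scores — is the implemented contract).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .cells import (
    AssignmentParams,
    BinningScheme,
    CellRecord,
    DEFAULT_LINEAGE_PROBES,
    assign_spots,
    build_cells,
    cells_to_dataframe,
    h_score,
)
from .io import (
    MultiChannelField,
    apply_exclusion,
    load_and_project,
    read_exclusion_geojson,
)
from .render import render_markup
from .segment import (
    NucleusRecord,
    SegmentationParams,
    nuclei_to_dataframe,
    segment_nuclei,
)
from .spots import (
    CalibrationError,
    SpotParams,
    SpotRecord,
    calibrate_unit_intensity,
    count_all_copies,
    detect_spots,
    spots_to_dataframe,
)

log = logging.getLogger("puncta")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, round-trippable through YAML."""

    pixel_size_um: float = 0.2
    channel_map: dict[str, str] = dc_field(
        default_factory=lambda: {"DAPI": "nuclear"}
    )
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    spot_defaults: SpotParams = dc_field(default_factory=SpotParams)
    spot_overrides: dict[str, SpotParams] = dc_field(default_factory=dict)
    assignment: AssignmentParams = dc_field(default_factory=AssignmentParams)
    binning: BinningScheme = dc_field(default_factory=BinningScheme)
    lineage_probes: dict[str, str] = dc_field(
        default_factory=lambda: dict(DEFAULT_LINEAGE_PROBES)
    )
    test_probes: list[str] | None = None
    denominator: str = "probe_positive"
    min_lineage_count: int = 2
    unit_intensity: dict[str, float] = dc_field(default_factory=dict)
    write_markup: bool = False
    seed: int = 0

    def spot_params_for(self, probe: str) -> SpotParams:
        return self.spot_overrides.get(probe, self.spot_defaults)

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["binning"] = {"minima": dict(self.binning.minima)}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d:
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "spot_defaults" in d:
            d["spot_defaults"] = SpotParams(**d["spot_defaults"])
        if "spot_overrides" in d:
            d["spot_overrides"] = {
                k: SpotParams(**v) for k, v in d["spot_overrides"].items()
            }
        if "assignment" in d:
            d["assignment"] = AssignmentParams(**d["assignment"])
        if "binning" in d:
            minima = {int(k): int(v) for k, v in d["binning"]["minima"].items()}
            d["binning"] = BinningScheme(minima=minima)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class FieldResult:
    name: str
    nuclei: list[NucleusRecord]
    spots: list[SpotRecord]
    cells: list[CellRecord]
    h_scores: dict[str, "object"]  # probe -> HScoreResult
    unit_intensities: dict[str, float]
    error: str | None = None

    def summary_dict(self) -> dict:
        return {
            "field": self.name,
            "n_nuclei": len(self.nuclei),
            "n_spots": len(self.spots),
            "n_cells": len(self.cells),
            "unit_intensities": self.unit_intensities,
            "h_scores": {
                probe: {
                    "denominator": hs.denominator,
                    "n_cells": hs.n_cells,
                    "percent_per_class": hs.percent_per_class,
                    "h_score": hs.h_score,
                }
                for probe, hs in self.h_scores.items()
            },
            "error": self.error,
        }


def process_field(
    field_: MultiChannelField,
    config: PipelineConfig,
    name: str = "field",
    nuclei: list[NucleusRecord] | None = None,
) -> FieldResult:
    """Quantify one in-memory field.

    ``nuclei`` may be injected (e.g. ground-truth nuclei) to bypass
    segmentation while keeping the rest of the pipeline identical.
    """
    if nuclei is None:
        nuclei = segment_nuclei(
            field_.counterstain, field_.pixel_size_um, config.segmentation
        )
    if field_.exclusion_mask is not None:
        nuclei = [n for n in nuclei if not field_.is_excluded(n.centroid_um)]
        # re-number so ids stay 1..n in row-major order
        for i, n in enumerate(nuclei, start=1):
            n.id = i
    log.info("%s: %d nuclei", name, len(nuclei))

    all_spots: list[SpotRecord] = []
    units: dict[str, float] = {}
    for probe, channel in field_.probe_channels.items():
        params = config.spot_params_for(probe)
        probe_spots = detect_spots(channel, field_.pixel_size_um, params, probe=probe)
        if field_.exclusion_mask is not None:
            probe_spots = [
                s for s in probe_spots if not field_.is_excluded(s.centroid_um)
            ]
        if probe in config.unit_intensity:
            unit = config.unit_intensity[probe]
        else:
            try:
                unit = calibrate_unit_intensity(
                    probe_spots, params.copy_intensity_threshold
                )
            except CalibrationError:
                if not probe_spots:
                    continue
                raise
        units[probe] = unit
        count_all_copies(probe_spots, unit, params)
        all_spots.extend(probe_spots)
        log.info("%s/%s: %d spots, unit intensity %.4f", name, probe, len(probe_spots), unit)

    assign_spots(nuclei, all_spots, config.assignment)
    cells = build_cells(
        nuclei,
        all_spots,
        config.lineage_probes,
        config.test_probes,
        config.binning,
        config.min_lineage_count,
    )
    probes_present = sorted({s.probe for s in all_spots})
    test_probes = config.test_probes or [
        p for p in probes_present if p not in config.lineage_probes
    ]
    scores = {}
    for probe in test_probes:
        try:
            scores[probe] = h_score(cells, probe, config.denominator, config.binning)
        except ValueError as exc:
            log.warning("%s/%s: H-score undefined (%s)", name, probe, exc)
    return FieldResult(
        name=name,
        nuclei=nuclei,
        spots=all_spots,
        cells=cells,
        h_scores=scores,
        unit_intensities=units,
    )


def _sample_summary(
    sample: str,
    field_results: Sequence[FieldResult],
    config: PipelineConfig,
) -> dict:
    """Pool cells across a sample's fields, then score the pooled table."""
    pooled: list[CellRecord] = []
    for fr in field_results:
        if fr.error is None:
            pooled.extend(fr.cells)
    probes = sorted({p for fr in field_results for p in fr.h_scores})
    scores = {}
    for probe in probes:
        try:
            hs = h_score(pooled, probe, config.denominator, config.binning)
            scores[probe] = {
                "denominator": hs.denominator,
                "n_cells": hs.n_cells,
                "percent_per_class": hs.percent_per_class,
                "h_score": hs.h_score,
            }
        except ValueError:
            pass
    return {
        "sample": sample,
        "n_fields": len(field_results),
        "n_cells": len(pooled),
        "h_scores": scores,
    }


def run_pipeline(
    config: PipelineConfig,
    inputs: Mapping[str, Sequence[str | Path]],
    out_dir: str | Path,
) -> dict:
    """Run the full pipeline over samples → fields and write result files.

    ``inputs`` maps a sample id to its field image paths.  A sidecar
    ``<field>.geojson`` next to a TIFF is read as exclusion polygons.
    A failing field is reported (with its stage) and skipped; remaining
    fields still run.  Returns the overall summary dict, which is also
    written as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log.info("pipeline start: %d samples, seed %d", len(inputs), config.seed)

    field_summaries = []
    sample_summaries = []
    for sample, paths in inputs.items():
        sample_dir = out / sample
        sample_dir.mkdir(parents=True, exist_ok=True)
        results: list[FieldResult] = []
        for path in paths:
            path = Path(path)
            fname = path.stem
            try:
                field_ = load_and_project(
                    path, config.channel_map, config.pixel_size_um
                )
                geo = path.with_suffix(".geojson")
                if geo.exists():
                    field_ = apply_exclusion(field_, read_exclusion_geojson(geo))
                fr = process_field(field_, config, name=f"{sample}/{fname}")
            except Exception as exc:  # keep processing remaining fields
                log.error("field %s failed: %s", path, exc)
                fr = FieldResult(
                    name=f"{sample}/{fname}",
                    nuclei=[],
                    spots=[],
                    cells=[],
                    h_scores={},
                    unit_intensities={},
                    error=f"{type(exc).__name__}: {exc}",
                )
            results.append(fr)
            if fr.error is None:
                nuclei_to_dataframe(fr.nuclei).to_csv(
                    sample_dir / f"{fname}_nuclei.csv", index=False
                )
                spots_to_dataframe(fr.spots).to_csv(
                    sample_dir / f"{fname}_spots.csv", index=False
                )
                cells_to_dataframe(fr.cells).to_csv(
                    sample_dir / f"{fname}_cells.csv", index=False
                )
                if config.write_markup:
                    try:
                        for probe in fr.h_scores:
                            render_markup(
                                field_,
                                fr.cells,
                                probe,
                                sample_dir / f"{fname}_markup_{probe}.png",
                            )
                    except Exception as exc:
                        log.warning("markup for %s failed: %s", fname, exc)
            field_summaries.append(fr.summary_dict())
        sample_summaries.append(_sample_summary(sample, results, config))
        with open(sample_dir / "sample_summary.json", "w") as fh:
            json.dump(sample_summaries[-1], fh, indent=2, sort_keys=True)

    summary = {
        "seed": config.seed,
        "fields": field_summaries,
        "samples": sample_summaries,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def discover_inputs(root: str | Path) -> dict[str, list[Path]]:
    """Interpret a directory tree ``root/<sample>/*.tif`` as pipeline input."""
    root = Path(root)
    inputs: dict[str, list[Path]] = {}
    for sample_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        tiffs = sorted(
            list(sample_dir.glob("*.tif")) + list(sample_dir.glob("*.tiff"))
        )
        if tiffs:
            inputs[sample_dir.name] = tiffs
    return inputs
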