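"""Synthetic multiplexed smFISH field generator with known ground truth.

Emulates a confocal field of DAPI-stained nuclei plus one channel per
RNAscope-style probe.  Single transcripts are rendered as diffraction-
limited 2-D Gaussians of fixed integrated intensity (the unit copy
intensity); a k-copy cluster is k such Gaussians superposed at one site.
Owned spots are placed within a small disk around the owner nucleus
centroid so that the ground truth is consistent with the 25 µm proximity
assignment rule.  Everything the generator draws is recorded in a
:class:`GroundTruth` object so that detection, copy decomposition and
assignment can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .io import COUNTERSTAIN, MultiChannelField, save_field

#: hard cap on owned-spot placement radius, matching the assignment rule (µm)
MAX_PLACEMENT_RADIUS_UM = 25.0


@dataclass(frozen=True)
class ProbeSpec:
    """One probe channel: expression level and clustering behaviour.

    mean_copies
        Mean transcript copies per positive cell (negative-binomial draw).
    fraction_positive
        Fraction of cells expressing the probe at all.
    cluster_fraction
        Probability that a remaining batch of copies is deposited as a
        multi-copy cluster site rather than an isolated single punctum.
    """

    name: str
    mean_copies: float = 5.0
    fraction_positive: float = 1.0
    cluster_fraction: float = 0.3


@dataclass
class SynthConfig:
    """Configuration of one synthetic field (defaults = study conditions)."""

    field_size_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.2
    n_nuclei: int = 20
    nucleus_radius_um: tuple[float, float] = (3.0, 5.0)
    probe_specs: tuple[ProbeSpec, ...] = (ProbeSpec("PPIB"),)
    psf_sigma_um: float = 0.3
    unit_copy_intensity: float = 1.5
    background_level: float = 0.02
    noise_sd: float = 0.01
    autofluorescent_blob_rate: float = 0.0
    autofluorescence_channel: str | None = None
    spot_placement_radius_um: float = 6.0
    copies_dispersion: float = 4.0  # NB size parameter for (copies - 1)
    cluster_extra_mean: float = 1.5  # cluster site holds 2 + Poisson(this)
    n_stray_spots: int = 0  # unowned background spots per probe
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if any(s <= 0 for s in self.field_size_px):
            raise ValueError("field_size_px must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        lo, hi = self.nucleus_radius_um
        if lo <= 0 or hi < lo:
            raise ValueError("nucleus_radius_um must be a positive range")
        if self.psf_sigma_um <= 0 or self.unit_copy_intensity <= 0:
            raise ValueError("psf_sigma_um and unit_copy_intensity must be positive")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background and noise levels must be non-negative")
        if self.autofluorescent_blob_rate < 0:
            raise ValueError("autofluorescent_blob_rate must be non-negative")
        if self.spot_placement_radius_um <= 0:
            raise ValueError("spot_placement_radius_um must be positive")
        if self.n_stray_spots < 0:
            raise ValueError("n_stray_spots must be non-negative")
        for spec in self.probe_specs:
            if spec.mean_copies < 0 or not (0 <= spec.fraction_positive <= 1):
                raise ValueError(f"invalid probe spec {spec.name!r}")
            if not (0 <= spec.cluster_fraction <= 1):
                raise ValueError(f"invalid cluster_fraction for {spec.name!r}")


@dataclass(frozen=True)
class TrueNucleus:
    id: int
    centroid_um: tuple[float, float]  # (x, y)
    radius_um: float


@dataclass(frozen=True)
class TrueSpot:
    probe: str
    centroid_um: tuple[float, float]  # (x, y)
    copies: int
    cell_id: int | None  # None for stray background spots


@dataclass
class GroundTruth:
    """Everything the generator drew, for exact scoring of the pipeline."""

    nuclei: list[TrueNucleus] = field(default_factory=list)
    cell_probe_copies: dict[tuple[int, str], int] = field(default_factory=dict)
    spot_truth: list[TrueSpot] = field(default_factory=list)

    def total_copies(self, probe: str, owned_only: bool = False) -> int:
        return sum(
            s.copies
            for s in self.spot_truth
            if s.probe == probe and (s.cell_id is not None or not owned_only)
        )

    def spot_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe": [s.probe for s in self.spot_truth],
                "x_um": [s.centroid_um[0] for s in self.spot_truth],
                "y_um": [s.centroid_um[1] for s in self.spot_truth],
                "copies": [s.copies for s in self.spot_truth],
                "cell_id": pd.array(
                    [s.cell_id for s in self.spot_truth], dtype="Int64"
                ),
            }
        )

    def cell_frame(self) -> pd.DataFrame:
        probes = sorted({p for (_, p) in self.cell_probe_copies})
        rows = []
        for nuc in self.nuclei:
            row: dict = {
                "cell_id": nuc.id,
                "x_um": nuc.centroid_um[0],
                "y_um": nuc.centroid_um[1],
                "radius_um": nuc.radius_um,
            }
            for p in probes:
                row[f"copies_{p}"] = self.cell_probe_copies.get((nuc.id, p), 0)
            rows.append(row)
        return pd.DataFrame(rows)


def _place_nuclei(cfg: SynthConfig, rng: np.random.Generator) -> list[TrueNucleus]:
    """Rejection-sample non-overlapping nucleus centres and radii."""
    h, w = cfg.field_size_px
    s = cfg.pixel_size_um
    lo, hi = cfg.nucleus_radius_um
    margin_um = 1.0
    nuclei: list[TrueNucleus] = []
    tries = 0
    while len(nuclei) < cfg.n_nuclei:
        tries += 1
        if tries > 20000:
            raise RuntimeError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei; "
                "reduce density or radii"
            )
        r = rng.uniform(lo, hi)
        # keep the whole nucleus plus the spot placement disk inside the field
        pad = r + margin_um
        x = rng.uniform(pad, w * s - pad)
        y = rng.uniform(pad, h * s - pad)
        ok = all(
            np.hypot(x - n.centroid_um[0], y - n.centroid_um[1])
            >= r + n.radius_um + margin_um
            for n in nuclei
        )
        if ok:
            nuclei.append(TrueNucleus(len(nuclei) + 1, (x, y), r))
    return nuclei


def _render_nuclei(
    cfg: SynthConfig, nuclei: Sequence[TrueNucleus], rng: np.random.Generator
) -> np.ndarray:
    """Draw nuclei as filled ellipses with per-nucleus brightness, smoothed."""
    h, w = cfg.field_size_px
    s = cfg.pixel_size_um
    im = np.zeros((h, w), dtype=np.float64)
    for nuc in nuclei:
        # mild, area-preserving eccentricity so roundness stays high
        q = rng.uniform(0.75, 1.0)
        a_px = nuc.radius_um / np.sqrt(q) / s
        b_px = nuc.radius_um * np.sqrt(q) / s
        theta = rng.uniform(0, np.pi)
        level = rng.uniform(0.5, 0.8)
        cx, cy = nuc.centroid_um
        rr, cc = draw_ellipse(
            cy / s - 0.5, cx / s - 0.5, a_px, b_px, shape=(h, w), rotation=theta
        )
        im[rr, cc] = np.maximum(im[rr, cc], level)
    return ndi.gaussian_filter(im, sigma=1.5)


def _gaussian_stamp(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    sigma_px: float,
    amplitude: float,
    out: np.ndarray,
) -> None:
    """Add a 2-D Gaussian of given integrated intensity into ``out`` in place.

    The stamp is normalized so that the rendered (in-window) pixel sum is
    exactly ``amplitude``, which makes integrated-intensity bookkeeping exact.
    """
    r0, c0 = center_px  # fractional pixel indices (pixel-centre convention)
    half = int(np.ceil(5 * sigma_px))
    rlo = max(0, int(np.floor(r0)) - half)
    rhi = min(shape[0], int(np.floor(r0)) + half + 1)
    clo = max(0, int(np.floor(c0)) - half)
    chi = min(shape[1], int(np.floor(c0)) + half + 1)
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    g = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma_px**2))
    total = g.sum()
    if total <= 0:
        return
    out[rlo:rhi, clo:chi] += amplitude * g / total


def _partition_copies(
    total: int, cluster_fraction: float, extra_mean: float, rng: np.random.Generator
) -> list[int]:
    """Split a cell's copy total into spot sites (singles and clusters)."""
    sites: list[int] = []
    remaining = total
    while remaining > 0:
        if remaining >= 2 and rng.random() < cluster_fraction:
            size = min(remaining, 2 + rng.poisson(extra_mean))
        else:
            size = 1
        sites.append(int(size))
        remaining -= size
    return sites


def _draw_copies(
    spec: ProbeSpec, dispersion: float, rng: np.random.Generator
) -> int:
    """Copies for one positive cell: 1 + negative binomial around the mean.

    The negative-binomial form is a modelling choice (flagged in
    :class:`SynthConfig`); positive cells always carry at least one copy.
    """
    m = max(spec.mean_copies - 1.0, 0.0)
    if m == 0:
        return 1
    p = dispersion / (dispersion + m)
    return 1 + int(rng.negative_binomial(dispersion, p))


def generate_field(config: SynthConfig) -> tuple[MultiChannelField, GroundTruth]:
    """Render one synthetic field and its exhaustive ground truth.

    Returns a :class:`MultiChannelField` whose first channel is the DAPI
    counterstain and remaining channels are one per probe, all clipped to
    [0, 1], plus the :class:`GroundTruth` bookkeeping.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.field_size_px
    s = config.pixel_size_um
    sigma_px = config.psf_sigma_um / s

    truth = GroundTruth()
    truth.nuclei = _place_nuclei(config, rng)

    dapi = _render_nuclei(config, truth.nuclei, rng)

    placement_r = min(config.spot_placement_radius_um, MAX_PLACEMENT_RADIUS_UM)
    probe_images: dict[str, np.ndarray] = {}
    for spec in config.probe_specs:
        im = np.zeros((h, w), dtype=np.float64)
        for nuc in truth.nuclei:
            if rng.random() >= spec.fraction_positive:
                continue
            total = _draw_copies(spec, config.copies_dispersion, rng)
            truth.cell_probe_copies[(nuc.id, spec.name)] = total
            sites = _partition_copies(
                total, spec.cluster_fraction, config.cluster_extra_mean, rng
            )
            for size in sites:
                # uniform in a disk around the owner centroid, inside the field
                r = placement_r * np.sqrt(rng.random())
                theta = rng.uniform(0, 2 * np.pi)
                x = float(np.clip(nuc.centroid_um[0] + r * np.cos(theta), s, (w - 1) * s))
                y = float(np.clip(nuc.centroid_um[1] + r * np.sin(theta), s, (h - 1) * s))
                truth.spot_truth.append(TrueSpot(spec.name, (x, y), size, nuc.id))
                _gaussian_stamp(
                    (h, w),
                    (y / s - 0.5, x / s - 0.5),
                    sigma_px,
                    size * config.unit_copy_intensity,
                    im,
                )
        for _ in range(config.n_stray_spots):
            x = rng.uniform(s, (w - 1) * s)
            y = rng.uniform(s, (h - 1) * s)
            truth.spot_truth.append(TrueSpot(spec.name, (x, y), 1, None))
            _gaussian_stamp(
                (h, w), (y / s - 0.5, x / s - 0.5), sigma_px, config.unit_copy_intensity, im
            )
        probe_images[spec.name] = im

    # autofluorescent aggregates: large dim blobs in one configurable channel,
    # emulating the high green-channel background of aggregate-rich tissue
    if config.autofluorescent_blob_rate > 0 and config.autofluorescence_channel:
        ch = config.autofluorescence_channel
        if ch not in probe_images:
            raise ValueError(f"autofluorescence_channel {ch!r} is not a probe")
        n_blobs = rng.poisson(config.autofluorescent_blob_rate)
        for _ in range(n_blobs):
            blob_r_um = rng.uniform(2.0, 4.0)  # area >> 0.45 µm²
            level = rng.uniform(0.03, 0.08)
            x = rng.uniform(0, (w - 1) * s)
            y = rng.uniform(0, (h - 1) * s)
            rr, cc = np.mgrid[0:h, 0:w]
            d2 = ((rr + 0.5) * s - y) ** 2 + ((cc + 0.5) * s - x) ** 2
            probe_images[ch] += level * np.exp(-d2 / (2 * blob_r_um**2))

    channels: dict[str, np.ndarray] = {"DAPI": dapi}
    channel_probe_map: dict[str, str] = {"DAPI": COUNTERSTAIN}
    for spec in config.probe_specs:
        channels[spec.name] = probe_images[spec.name]
        channel_probe_map[spec.name] = spec.name

    for name, im in channels.items():
        im = im + config.background_level
        if config.noise_sd > 0:
            im = im + rng.normal(0.0, config.noise_sd, size=im.shape)
        channels[name] = np.clip(im, 0.0, 1.0)

    field_ = MultiChannelField(
        channels=channels,
        pixel_size_um=s,
        channel_probe_map=channel_probe_map,
    )
    return field_, truth


def write_synthetic_dataset(
    config: SynthConfig, out_dir: str | Path, name: str = "field"
) -> dict[str, Path]:
    """Write a field as TIFF + truth CSVs + the config echoed as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    field_, truth = generate_field(config)
    paths = {
        "tiff": out / f"{name}.tif",
        "spot_truth": out / f"{name}_spot_truth.csv",
        "cell_truth": out / f"{name}_cell_truth.csv",
        "config": out / f"{name}_config.yaml",
    }
    save_field(field_, paths["tiff"])
    truth.spot_frame().to_csv(paths["spot_truth"], index=False)
    truth.cell_frame().to_csv(paths["cell_truth"], index=False)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["probe_specs"] = [dataclasses.asdict(p) for p in config.probe_specs]
    cfg_dict["channel_order"] = list(field_.channel_probe_map)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=False)
    return paths
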