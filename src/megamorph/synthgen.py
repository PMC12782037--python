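"""Synthetic specimen generator: taxonomy, allometric masses, two-view frames, OTU tables.

Emulates the outputs of a single-specimen megabarcoding + imaging study:

* a four-rank taxonomy (order / family / genus / species),
* specimens whose dry mass follows a species-specific allometric power law
  ``m = c_s * L**b_s * exp(eps)`` with lognormal noise,
* multi-frame two-camera silhouette images of species-distinct shapes
  sinking at random in-plane orientations,
* balance readings with additive noise, quantization to the scale
  readability, and the possibility of non-positive records near the
  detection limit,
* per-specimen OTU read tables with a dominant OTU, contaminants, and
  injected failure modes (insufficient reads, order mismatch, no
  species-level hit) recorded in a truth ledger.

All randomness flows from one root seed through named substreams so each
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

# Closed set of order names; the first three are the EPT water-quality
# indicator orders, extras allow larger taxonomies.
ORDER_POOL = (
    "Ephemeroptera",
    "Plecoptera",
    "Trichoptera",
    "Diptera",
    "Coleoptera",
    "Odonata",
)

# Non-target taxa (gut content / parasite analogues) used for contaminant
# OTUs that the macroinvertebrate filter is expected to remove.
NONTARGET_ORDER_POOL = ("Nematoda", "Rotifera", "Fungi_incertae", "Bacteria_env")


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named RNG substream derived from one root seed.

    Stage-level reproducibility: the stream for e.g. ``("frames", 17)`` does
    not depend on how many draws other stages made.
    """
    h = hashlib.sha256(f"{name}:{index}".encode()).digest()
    key = int.from_bytes(h[:8], "little")
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


@dataclass(frozen=True)
class TaxonLabel:
    """One species with its full ancestry; ranks may be empty strings when truncated."""

    species: str
    genus: str
    family: str
    order: str

    def at_rank(self, rank: str) -> str:
        return getattr(self, rank)


@dataclass(frozen=True)
class ShapeDescriptor:
    """Parametric silhouette family for one species.

    elongation: body length / body width ratio (1 = circular).
    taper: abdomen taper exponent (1 = ellipse, >1 = pointier rear).
    n_leg_pairs: lateral leg pairs drawn as thin limbs.
    n_cerci: thin tail filaments at the rear.
    cased: rectangular case covering the abdomen (case-building taxa only).
    dorsoventral: camera-1 width multiplier (perpendicular view projection).
    """

    elongation: float
    taper: float = 1.0
    n_leg_pairs: int = 0
    n_cerci: int = 0
    waist: bool = False  # constriction between head and abdomen
    cased: bool = False
    dorsoventral: float = 0.75


@dataclass(frozen=True)
class AllometryParams:
    """Allometric mass law and weighing model parameters.

    coeff_mg / exponent: per-species ``c_s`` (mg per mm^b) and ``b_s``.
    sigma_log: lognormal mass noise sd (log-mg).
    detection_limit_mg: balance detection limit (metadata; exclusion happens
        downstream on measured mass <= 0).
    readability_mg: quantization step of the balance.
    weigh_noise_sd_mg: additive Normal noise of one weighing, before
        quantization; reproduces occasional negative records for tiny
        specimens.
    """

    coeff_mg: dict[str, float]
    exponent: dict[str, float]
    sigma_log: float = 0.1
    detection_limit_mg: float = 0.01
    readability_mg: float = 0.01
    weigh_noise_sd_mg: float = 0.005

    def __post_init__(self) -> None:
        for sp, c in self.coeff_mg.items():
            if c <= 0:
                raise ValueError(f"allometric coefficient must be > 0 (species {sp!r})")
        for sp, b in self.exponent.items():
            if not 1.0 <= b <= 4.0:
                raise ValueError(f"allometric exponent must be in [1, 4] (species {sp!r})")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.detection_limit_mg < 0:
            raise ValueError("detection_limit_mg must be >= 0")
        if self.readability_mg <= 0:
            raise ValueError("readability_mg must be > 0")


@dataclass(frozen=True)
class LengthParams:
    """Per-species body-length distribution: lognormal around a species median.

    The log-deviation is truncated at ``max_sigmas`` so the silhouette of an
    extreme draw still fits a fixed frame size (growth past that range is
    biologically implausible within one larval cohort anyway).
    """

    median_mm: dict[str, float]
    sigma_log: float = 0.15
    max_sigmas: float = 2.5


@dataclass(frozen=True)
class SpecimenTruth:
    specimen_id: str
    taxon: TaxonLabel
    length_mm: float
    mass_mg: float
    shape: ShapeDescriptor
    plate: int
    well: str


@dataclass
class FrameImage:
    """One grayscale frame of one specimen from one camera.

    pixels: uint8, row-major, origin top-left; dark specimen on light
    background. ``nontarget_truth`` marks injected junk frames (bubbles,
    debris analogues) in the generator's ledger sense.
    """

    pixels: np.ndarray
    specimen_id: str
    camera_id: int
    frame_index: int
    px_per_mm: float
    nontarget_truth: bool = False

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("frame pixels must be a non-empty 2-D grid")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if self.camera_id not in (0, 1):
            raise ValueError("camera_id must be 0 or 1")


@dataclass(frozen=True)
class OTURecord:
    sample_id: str
    specimen_id: str
    otu_id: str
    read_count: int
    taxonomy: TaxonLabel
    macroinvertebrate: bool = True

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")


# ---------------------------------------------------------------------------
# taxonomy


def generate_taxonomy(
    n_species: int, n_genera: int, n_families: int, n_orders: int, seed: int
) -> list[TaxonLabel]:
    """Random four-rank taxonomy with exact rank counts.

    Each rank maps surjectively onto the next higher rank, so every genus,
    family and order has at least one descendant species.
    """
    counts = (n_species, n_genera, n_families, n_orders)
    if not (n_species >= n_genera >= n_families >= n_orders >= 1):
        raise ValueError(f"rank counts must satisfy species >= genus >= family >= order >= 1, got {counts}")
    if n_orders > len(ORDER_POOL):
        raise ValueError(f"at most {len(ORDER_POOL)} orders supported, got {n_orders}")
    rng = substream(seed, "taxonomy")

    def surjection(n_child: int, n_parent: int) -> np.ndarray:
        # each parent gets one child, remaining children drawn uniformly
        parents = np.concatenate([np.arange(n_parent), rng.integers(0, n_parent, n_child - n_parent)])
        return rng.permutation(parents)

    fam_to_ord = surjection(n_families, n_orders)
    gen_to_fam = surjection(n_genera, n_families)
    spe_to_gen = surjection(n_species, n_genera)

    orders = [ORDER_POOL[i] for i in range(n_orders)]
    families = [f"{orders[fam_to_ord[i]][:4]}idae{i:02d}" for i in range(n_families)]
    genera = [f"Genus{i:02d}" for i in range(n_genera)]
    out = []
    for s in range(n_species):
        g = int(spe_to_gen[s])
        f = int(gen_to_fam[g])
        o = int(fam_to_ord[f])
        out.append(TaxonLabel(f"{genera[g]}_sp{s:02d}", genera[g], families[f], orders[o]))
    return out


def default_shape_library(taxonomy: list[TaxonLabel]) -> dict[str, ShapeDescriptor]:
    """Species-specific silhouette parameters on a coarse grid.

    The grid spacing is deliberately wide so classes are visually separable
    at desk-scale image resolution: elongation, taper, leg pairs and cerci
    jointly give every species a distinct parameter vector. Cases occur only
    in the caddisfly analogue (Trichoptera).
    """
    lib: dict[str, ShapeDescriptor] = {}
    for i, t in enumerate(taxonomy):
        cased = t.order == "Trichoptera" and (i % 2 == 0)
        lib[t.species] = ShapeDescriptor(
            # three strong axes (2x elongation gap, legs on/off, head bulb
            # on/off) cycle through 8 distinct combinations; species 8+ shift
            # the elongation base so the cycle restarts visually offset
            elongation=(1.6, 3.4)[i % 2] * (1.0 + 0.55 * (i // 8)),
            taper=1.5,
            n_leg_pairs=3 * ((i // 2) % 2),
            waist=bool((i // 4) % 2),
            n_cerci=(2 if t.order == "Ephemeroptera" else 0),
            cased=cased,
            # close enough to 1 that the two views of one species stay more
            # similar to each other than to the neighboring elongation class
            dorsoventral=0.8 + 0.04 * (i % 4),
        )
    return lib


def default_allometry(taxonomy: list[TaxonLabel], seed: int = 0) -> AllometryParams:
    """Per-species power-law parameters spanning a realistic mg range."""
    rng = substream(seed, "allometry")
    coeff = {t.species: float(np.exp(rng.uniform(np.log(0.015), np.log(0.06)))) for t in taxonomy}
    expo = {t.species: float(rng.uniform(2.2, 3.0)) for t in taxonomy}
    return AllometryParams(coeff_mg=coeff, exponent=expo)


def default_lengths(taxonomy: list[TaxonLabel]) -> LengthParams:
    n = len(taxonomy)
    medians = np.exp(np.linspace(np.log(3.5), np.log(9.0), max(n, 2)))[:n]
    return LengthParams(median_mm={t.species: float(m) for t, m in zip(taxonomy, medians)})


# ---------------------------------------------------------------------------
# specimens and weighing


def generate_specimens(
    taxonomy: list[TaxonLabel],
    n_per_species: int,
    allometry: AllometryParams,
    lengths: LengthParams,
    seed: int,
    shapes: dict[str, ShapeDescriptor] | None = None,
) -> list[SpecimenTruth]:
    """Draw specimens with lognormal lengths and allometric lognormal masses."""
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    shapes = shapes if shapes is not None else default_shape_library(taxonomy)
    rng = substream(seed, "specimens")
    out: list[SpecimenTruth] = []
    idx = 0
    for t in taxonomy:
        c, b = allometry.coeff_mg[t.species], allometry.exponent[t.species]
        med = lengths.median_mm[t.species]
        base_shape = shapes[t.species]
        for _ in range(n_per_species):
            z = np.clip(rng.normal(), -lengths.max_sigmas, lengths.max_sigmas)
            L = float(med * np.exp(lengths.sigma_log * z))
            eps = float(rng.normal(0.0, allometry.sigma_log))
            m = float(c * L**b * np.exp(eps))
            # per-specimen dorsoventral projection factor around the species mean
            dv = float(np.clip(base_shape.dorsoventral + rng.normal(0.0, 0.03), 0.4, 1.0))
            plate, pos = divmod(idx, 96)
            well = f"{'ABCDEFGH'[pos % 8]}{pos // 8 + 1}"
            out.append(
                SpecimenTruth(
                    f"S{idx:04d}", t, L, m, replace(base_shape, dorsoventral=dv), plate + 1, well
                )
            )
            idx += 1
    return out


def weigh(specimen: SpecimenTruth, allometry: AllometryParams, seed: int) -> float:
    """One balance reading: true mass + Normal noise, quantized to readability.

    Non-positive readings are possible for masses near the detection limit
    and are returned as-is; exclusion is a curation decision downstream.
    """
    if specimen.mass_mg <= 0:
        raise ValueError(f"specimen {specimen.specimen_id} has non-positive true mass")
    rng = substream(seed, "weights", int(specimen.specimen_id.lstrip("S"), 10))
    raw = specimen.mass_mg + rng.normal(0.0, allometry.weigh_noise_sd_mg)
    r = allometry.readability_mg
    return float(np.round(raw / r) * r)


# ---------------------------------------------------------------------------
# rendering


def _silhouette_mask(
    shape: ShapeDescriptor,
    length_mm: float,
    px_per_mm: float,
    height: int,
    width: int,
    angle_rad: float,
    width_scale: float,
) -> np.ndarray:
    """Rasterize the parametric silhouette at one in-plane rotation.

    The body is an ellipse-like closed curve of half-length a and half-width
    b(x) tapering toward the rear; appendages (legs, cerci) and the optional
    case stay within the body's major-axis extent so the maximum Feret
    diameter of the clean mask equals ``length_mm * px_per_mm`` for
    elongated species.
    """
    a = length_mm * px_per_mm / 2.0
    b = max(a / shape.elongation * width_scale, 1.6)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    yr, xr = yy - cy, xx - cx
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    # rotate pixel coordinates into the canonical (body-axis) frame
    u = ca * xr + sa * yr
    v = -sa * xr + ca * yr

    with np.errstate(invalid="ignore"):
        t = np.clip(u / a, -1.0, 1.0)
        # tapered half-width profile; taper applies to the rear half (u < 0)
        prof = np.sqrt(np.maximum(1.0 - t**2, 0.0))
        rear = u < 0
        prof = np.where(rear, prof**shape.taper, prof)
        mask = (np.abs(u) <= a) & (np.abs(v) <= b * prof)

    lw = max(2.0, 0.12 * b)  # limb half-thickness in px (survives downscaling)
    if shape.n_leg_pairs:
        for k in range(shape.n_leg_pairs):
            ux = a * (0.15 + 0.25 * k)  # attachment along front half
            reach = min(2.2 * b, 0.92 * np.sqrt(max(a**2 - ux**2, 0.0)))
            leg = (np.abs(u - ux) <= lw) & (np.abs(v) <= reach)
            mask |= leg
    if shape.n_cerci:
        for k in range(shape.n_cerci):
            voff = b * (0.5 * (k - (shape.n_cerci - 1) / 2.0))
            cer = (u <= -0.55 * a) & (u >= -0.98 * a) & (np.abs(v - voff) <= lw)
            mask |= cer
    if shape.cased:
        case = (u >= -0.9 * a) & (u <= 0.1 * a) & (np.abs(v) <= 1.45 * b)
        mask |= case
    if shape.waist:
        # deep constriction behind the head, cut through body, limbs and
        # case alike so it stays visible for every body plan; subtractive,
        # so the maximum Feret extent is untouched, and never pinched below
        # ~3 px so the silhouette stays connected
        band = (u >= 0.35 * a) & (u <= 0.55 * a)
        keep = np.maximum(0.35 * b * prof, 1.6)
        mask &= ~(band & (np.abs(v) > keep))
    return mask


def render_frames(
    specimen: SpecimenTruth,
    n_frames: int,
    image_size: tuple[int, int],
    px_per_mm: float,
    junk_rate: float,
    seed: int,
    noise_sd: float = 0.0,
) -> list[FrameImage]:
    """Render two-view frames of one specimen at random in-plane rotations.

    Frames alternate between camera 0 (lateral view) and camera 1 (the
    perpendicular view: same body with width scaled by the specimen's
    dorsoventral factor). With probability ``junk_rate`` a frame is replaced
    by a non-target blob and flagged in metadata.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    height, width = image_size
    extent = specimen.length_mm * px_per_mm
    need = int(np.ceil(extent)) + 8
    if need > min(height, width):
        raise ValueError(
            f"silhouette of specimen {specimen.specimen_id} "
            f"({extent:.0f} px) exceeds frame bounds {image_size}; "
            f"need at least {need}x{need}"
        )
    rng = substream(seed, "frames", int(specimen.specimen_id.lstrip("S"), 10))
    frames: list[FrameImage] = []
    per_cam_index = [0, 0]
    for i in range(n_frames):
        cam = i % 2
        angle = rng.uniform(0.0, 2.0 * np.pi)
        junk = bool(rng.random() < junk_rate)
        if junk:
            mask = _junk_blob(height, width, rng)
        else:
            wscale = 1.0 if cam == 0 else specimen.shape.dorsoventral
            mask = _silhouette_mask(
                specimen.shape, specimen.length_mm, px_per_mm, height, width, angle, wscale
            )
        img = np.full((height, width), 245.0)
        img[mask] = 15.0
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, img.shape)
        frames.append(
            FrameImage(
                pixels=np.clip(img, 0, 255).astype(np.uint8),
                specimen_id=specimen.specimen_id,
                camera_id=cam,
                frame_index=per_cam_index[cam],
                px_per_mm=px_per_mm,
                nontarget_truth=junk,
            )
        )
        per_cam_index[cam] += 1
    return frames


def _junk_blob(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """A small off-center disk emulating a bubble or debris fragment."""
    r = rng.uniform(2.0, 5.0)
    cy = rng.uniform(height * 0.2, height * 0.8)
    cx = rng.uniform(width * 0.2, width * 0.8)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


# ---------------------------------------------------------------------------
# OTU tables


@dataclass(frozen=True)
class ReadParams:
    """Read-count model: heavy-tailed dominant reads, much smaller contaminants."""

    dominant_median: float = 2.0e5
    dominant_sigma_log: float = 0.5
    contaminant_median: float = 2.0e3
    contaminant_sigma_log: float = 1.0
    mean_contaminants: float = 4.0
    frac_contaminants_nontarget: float = 0.7
    min_contaminant_reads: int = 1
    read_threshold: int = 1000  # the downstream discard threshold the noreads mode undercuts


@dataclass(frozen=True)
class FailureRates:
    p_noreads: float = 0.0
    p_mismatch: float = 0.0
    p_nospecies: float = 0.0
    p_repeat: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_noreads, self.p_mismatch, self.p_nospecies, self.p_repeat):
            if not 0.0 <= p <= 1.0:
                raise ValueError("failure rates must lie in [0, 1]")
        if self.p_noreads + self.p_mismatch + self.p_nospecies > 1.0:
            raise ValueError("failure rates must sum to <= 1")


def generate_otu_table(
    specimens: list[SpecimenTruth],
    taxonomy: list[TaxonLabel],
    read_params: ReadParams,
    rates: FailureRates,
    seed: int,
) -> tuple[list[OTURecord], pd.DataFrame]:
    """Per-specimen OTU records plus the injected-status truth ledger.

    Each specimen yields one sample (two when a PCR repeat is simulated)
    containing a dominant OTU carrying its true taxonomy plus contaminant
    OTUs with lower reads. Failure modes are injected by construction:

    * ``noreads``   — dominant reads drawn below the read threshold,
    * ``mismatch``  — dominant taxonomy replaced by a species from another order,
    * ``nospecies`` — dominant taxonomy truncated above species rank.

    Macroinvertebrate contaminant reads are capped strictly below the
    dominant reads so the winner is unambiguous (well-separated regime).
    """
    rng = substream(seed, "otus")
    if rates.p_mismatch > 0 and len({t.order for t in taxonomy}) < 2:
        raise ValueError("order-mismatch injection needs a taxonomy with >= 2 orders")
    species_to_taxon = {t.species: t for t in taxonomy}
    records: list[OTURecord] = []
    ledger_rows = []
    for sp in specimens:
        u = rng.random()
        if u < rates.p_noreads:
            status = "noreads"
        elif u < rates.p_noreads + rates.p_mismatch:
            status = "mismatch"
        elif u < rates.p_noreads + rates.p_mismatch + rates.p_nospecies:
            status = "nospecies"
        else:
            status = "ok"
        repeat = bool(rng.random() < rates.p_repeat)
        sample_ids = [f"{sp.specimen_id}_a"] + ([f"{sp.specimen_id}_b"] if repeat else [])

        dom_taxon = species_to_taxon[sp.taxon.species]
        if status == "mismatch":
            others = [t for t in taxonomy if t.order != sp.taxon.order]
            dom_taxon = others[int(rng.integers(len(others)))]
        elif status == "nospecies":
            dom_taxon = replace(dom_taxon, species="")
        dom_otu = f"OTU_{dom_taxon.genus}_{dom_taxon.species or 'sp'}"

        dom_reads_per_sample = []
        for sid in sample_ids:
            if status == "noreads":
                dom_reads = int(rng.integers(0, read_params.read_threshold))
            else:
                dom_reads = int(
                    np.exp(rng.normal(np.log(read_params.dominant_median), read_params.dominant_sigma_log))
                )
            dom_reads_per_sample.append(dom_reads)
            if dom_reads > 0:
                records.append(OTURecord(sid, sp.specimen_id, dom_otu, dom_reads, dom_taxon, True))
            n_contam = int(rng.poisson(read_params.mean_contaminants))
            for c in range(n_contam):
                creads = int(
                    np.exp(
                        rng.normal(
                            np.log(read_params.contaminant_median), read_params.contaminant_sigma_log
                        )
                    )
                )
                creads = max(creads, read_params.min_contaminant_reads)
                if rng.random() < read_params.frac_contaminants_nontarget:
                    o = NONTARGET_ORDER_POOL[int(rng.integers(len(NONTARGET_ORDER_POOL)))]
                    tax = TaxonLabel("", "", "", o)
                    records.append(OTURecord(sid, sp.specimen_id, f"OTU_env{c:02d}_{o[:4]}", creads, tax, False))
                else:
                    other = taxonomy[int(rng.integers(len(taxonomy)))]
                    creads = min(creads, max(dom_reads - 1, 0))
                    if creads < read_params.min_contaminant_reads:
                        continue
                    records.append(
                        OTURecord(
                            sid, sp.specimen_id, f"OTU_{other.genus}_{other.species}", creads, other, True
                        )
                    )
        ledger_rows.append(
            {
                "specimen_id": sp.specimen_id,
                "injected_status": status,
                "repeat": repeat,
                "dominant_otu": dom_otu,
                "dominant_reads": max(dom_reads_per_sample),
            }
        )
    return records, pd.DataFrame(ledger_rows)


# ---------------------------------------------------------------------------
# tabular export


def specimens_frame(
    specimens: list[SpecimenTruth], allometry: AllometryParams, seed: int
) -> pd.DataFrame:
    """specimens.csv content: identity, taxonomy, true and measured mass."""
    rows = []
    for sp in specimens:
        rows.append(
            {
                "specimen_id": sp.specimen_id,
                "order": sp.taxon.order,
                "family": sp.taxon.family,
                "genus": sp.taxon.genus,
                "species": sp.taxon.species,
                "length_mm": sp.length_mm,
                "true_mass_mg": sp.mass_mg,
                "measured_mass_mg": weigh(sp, allometry, seed),
                "plate": sp.plate,
                "well": sp.well,
            }
        )
    return pd.DataFrame(rows)


def otu_frame(records: list[OTURecord]) -> pd.DataFrame:
    """otu_table.tsv content; empty string marks a missing (truncated) rank."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "specimen_id": [r.specimen_id for r in records],
            "otu_id": [r.otu_id for r in records],
            "reads": [r.read_count for r in records],
            "order": [r.taxonomy.order for r in records],
            "family": [r.taxonomy.family for r in records],
            "genus": [r.taxonomy.genus for r in records],
            "species": [r.taxonomy.species for r in records],
            "macroinvertebrate": [r.macroinvertebrate for r in records],
        }
    )


def morphology_frame(specimens: list[SpecimenTruth]) -> pd.DataFrame:
    """morphology.csv: the (always correct) morphological order identification."""
    return pd.DataFrame(
        {
            "specimen_id": [sp.specimen_id for sp in specimens],
            "morphological_order": [sp.taxon.order for sp in specimens],
        }
    )
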