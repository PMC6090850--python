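"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its consumer assumes and
returns the hidden ground truth alongside the data, so downstream
estimators (percent positive, responder fraction, concordance, nucleus
count) can be validated by parameter recovery without any external
downloads:

* ``gen_expression`` -- log-normal FPKM matrices with condition, lab and
  replicate structure and a tunable differentiation shift applied to a
  designated neutrophil-signature gene subset.
* ``gen_cytometry`` -- two-component log-normal fluorescence mixtures with
  a matched unstained control and a dead-cell viability channel.
* ``gen_tracks`` -- cell trajectories whose responder subset turns toward
  a gradient source after an uncaging stimulus (von Mises step angles).
* ``gen_genotypes`` -- genotype tables in which samples of one identity
  group are exact copies and groups differ at a tunable fraction of loci.
* ``gen_nuclei_image`` -- two-channel images of non-overlapping elliptical
  nuclei with a dead subset bright in the viability channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .chemotaxis import TrackSet
from .expression import ExpressionMatrix
from .genotype import GenotypeTable

__all__ = [
    "ExpressionGenSpec",
    "CytometryGenSpec",
    "TrackGenSpec",
    "GenotypeGenSpec",
    "NucleiImageSpec",
    "GeneratedExpression",
    "GeneratedCytometry",
    "GeneratedTracks",
    "GeneratedGenotypes",
    "GeneratedNucleiImage",
    "GenerationError",
    "gen_expression",
    "gen_cytometry",
    "gen_tracks",
    "gen_genotypes",
    "gen_nuclei_image",
]


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its geometric constraints."""


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionGenSpec:
    """Parameters of the synthetic FPKM generator.

    ``samples`` lists (species, lab, condition, replicate, day) tuples.
    ``differentiation_shift`` maps condition labels to a log10 effect added
    to a designated signature-gene subset; the per-condition shift makes
    correlation with a fully-shifted "primary neutrophil" condition grow
    monotonically with the applied shift.  Zeros are injected by masking
    the lowest-expressed ``zero_fraction`` of genes per sample, mimicking
    dropout of lowly expressed genes.
    """

    n_genes: int
    samples: Sequence[tuple]
    baseline_logmean: float = 0.5
    baseline_logsd: float = 1.0
    differentiation_shift: Mapping[str, float] = field(default_factory=dict)
    signature_fraction: float = 0.1
    zero_fraction: float = 0.05
    lab_effect_sd: float = 0.05
    noise_logsd: float = 0.1
    reference_species: str | None = "human"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.samples:
            raise ValueError("at least one sample required")
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValueError("zero_fraction must lie in [0, 1)")
        _check_fraction("signature_fraction", self.signature_fraction)


@dataclass(frozen=True)
class GeneratedExpression:
    matrix: ExpressionMatrix
    signature_genes: tuple          # hidden truth: genes carrying the shift


def gen_expression(spec: ExpressionGenSpec) -> GeneratedExpression:
    """Draw a log-normal FPKM matrix with condition/lab/replicate structure.

    Values are drawn normal on the log10 scale (gene baseline + lab offset
    + condition shift on signature genes + replicate noise) and
    exponentiated, so all values are nonnegative and finite; deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    gene_mean = rng.normal(spec.baseline_logmean, spec.baseline_logsd, spec.n_genes)
    n_sig = int(round(spec.signature_fraction * spec.n_genes))
    sig_idx = rng.choice(spec.n_genes, size=n_sig, replace=False)
    is_sig = np.zeros(spec.n_genes, dtype=bool)
    is_sig[sig_idx] = True

    labs = sorted({s[1] for s in spec.samples})
    lab_offset = dict(zip(labs, rng.normal(0.0, spec.lab_effect_sd, len(labs))))

    names, meta_rows, cols = [], [], []
    for species, lab, condition, replicate, day in spec.samples:
        name = f"{species}.{lab}.{condition}.d{day}.r{replicate}"
        if name in names:
            raise ValueError(f"duplicate sample design {name!r}")
        shift = float(spec.differentiation_shift.get(condition, 0.0))
        log_vals = (
            gene_mean
            + lab_offset[lab]
            + shift * is_sig
            + rng.normal(0.0, spec.noise_logsd, spec.n_genes)
        )
        vals = 10.0 ** log_vals
        n_zero = int(round(spec.zero_fraction * spec.n_genes))
        if n_zero:
            lowest = np.argsort(vals, kind="stable")[:n_zero]
            vals = vals.copy()
            vals[lowest] = 0.0
        names.append(name)
        cols.append(vals)
        meta_rows.append(
            {
                "species": species,
                "lab": lab,
                "condition": condition,
                "replicate": replicate,
                "day": day,
                "reference_group": species == spec.reference_species,
            }
        )
    values = pd.DataFrame(np.column_stack(cols), index=genes, columns=names)
    meta = pd.DataFrame(meta_rows, index=names)
    matrix = ExpressionMatrix(values, meta, scale="linear")
    return GeneratedExpression(matrix, tuple(genes[is_sig]))


# ---------------------------------------------------------------------------
# cytometry


@dataclass
class CytometryGenSpec:
    """Two-component log-normal fluorescence mixture with a dead subset.

    Marker intensities are ``10**N(location, scale)`` plus an additive
    autofluorescence offset; the positive and negative component locations
    are stated on the log10 scale, so their separation
    (``pos_location - neg_location``) is an explicit parameter.  The
    viability channel is an independent alive/dead mixture; the unstained
    control draws its marker channel entirely from the negative component
    and its viability channel from the alive component.
    """

    n_events: int = 10_000
    f_positive: float = 0.5
    neg_location: float = 1.0
    neg_scale: float = 0.3
    pos_location: float = 3.0
    pos_scale: float = 0.3
    autofluorescence_mean: float = 0.0
    f_dead: float = 0.05
    viability_neg_location: float = 1.0
    viability_pos_location: float = 3.0
    viability_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        _check_fraction("f_positive", self.f_positive)
        _check_fraction("f_dead", self.f_dead)

    @property
    def separation(self) -> float:
        return self.pos_location - self.neg_location


@dataclass(frozen=True)
class GeneratedCytometry:
    stained: pd.DataFrame            # columns: marker, viability
    unstained: pd.DataFrame          # matched negative control
    truth: pd.DataFrame              # hidden per-event is_positive, is_dead


def gen_cytometry(spec: CytometryGenSpec) -> GeneratedCytometry:
    """Draw a stained sample plus matched unstained control."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    is_positive = rng.random(n) < spec.f_positive
    is_dead = rng.random(n) < spec.f_dead

    log_marker = np.where(
        is_positive,
        rng.normal(spec.pos_location, spec.pos_scale, n),
        rng.normal(spec.neg_location, spec.neg_scale, n),
    )
    log_viab = np.where(
        is_dead,
        rng.normal(spec.viability_pos_location, spec.viability_scale, n),
        rng.normal(spec.viability_neg_location, spec.viability_scale, n),
    )
    stained = pd.DataFrame(
        {
            "marker": 10.0 ** log_marker + spec.autofluorescence_mean,
            "viability": 10.0 ** log_viab,
        }
    )
    unstained = pd.DataFrame(
        {
            "marker": 10.0 ** rng.normal(spec.neg_location, spec.neg_scale, n)
            + spec.autofluorescence_mean,
            "viability": 10.0 ** rng.normal(
                spec.viability_neg_location, spec.viability_scale, n
            ),
        }
    )
    truth = pd.DataFrame({"is_positive": is_positive, "is_dead": is_dead})
    return GeneratedCytometry(stained, unstained, truth)


# ---------------------------------------------------------------------------
# tracks


@dataclass
class TrackGenSpec:
    """Mixed-population chemotaxis trajectories.

    A ``f_responder`` fraction of cells turns toward the source after the
    stimulus, drawing step angles from a von Mises distribution centered on
    the instantaneous source direction with the given concentration
    (0 = uniform); non-responders and all pre-stimulus steps draw uniform
    angles.  ``angle_mode="per_cell"`` instead draws one persistent angular
    offset per responder cell.
    """

    n_cells: int = 100
    n_frames: int = 40
    frame_interval: float = 30.0          # seconds
    speed_mean: float = 5.0               # um per interval
    speed_sd: float = 1.5
    directional_concentration: float = 2.0
    f_responder: float = 0.7
    source: tuple[float, float] = (0.0, 0.0)
    stimulus_time: float = 300.0
    start_radius: tuple[float, float] = (100.0, 400.0)
    angle_mode: str = "per_step"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.directional_concentration < 0:
            raise ValueError("directional_concentration must be nonnegative")
        _check_fraction("f_responder", self.f_responder)
        if self.angle_mode not in ("per_step", "per_cell"):
            raise ValueError(f"unknown angle_mode {self.angle_mode!r}")


@dataclass(frozen=True)
class GeneratedTracks:
    trackset: TrackSet
    responders: pd.Series            # hidden truth: per-cell responder flag


def gen_tracks(spec: TrackGenSpec) -> GeneratedTracks:
    """Simulate trajectories with a responder subset biased toward the source."""
    rng = np.random.default_rng(spec.seed)
    source = np.asarray(spec.source, dtype=float)
    responder = rng.random(spec.n_cells) < spec.f_responder
    times = np.arange(spec.n_frames) * spec.frame_interval

    r0, r1 = spec.start_radius
    radii = rng.uniform(r0, r1, spec.n_cells)
    theta0 = rng.uniform(0.0, 2 * np.pi, spec.n_cells)
    starts = source + np.column_stack([radii * np.cos(theta0), radii * np.sin(theta0)])

    rows = []
    for c in range(spec.n_cells):
        pos = starts[c].copy()
        persistent_offset = None
        if spec.angle_mode == "per_cell" and responder[c] and spec.directional_concentration > 0:
            persistent_offset = rng.vonmises(0.0, spec.directional_concentration)
        cid = f"cell{c:04d}"
        rows.append((cid, times[0], pos[0], pos[1]))
        for t in times[1:]:
            step_len = max(rng.normal(spec.speed_mean, spec.speed_sd), 0.0)
            post = (t - spec.frame_interval) >= spec.stimulus_time
            biased = post and responder[c] and spec.directional_concentration > 0
            if biased:
                to_source = np.arctan2(*(source - pos)[::-1])
                if persistent_offset is not None:
                    heading = to_source + persistent_offset
                else:
                    heading = to_source + rng.vonmises(0.0, spec.directional_concentration)
            else:
                heading = rng.uniform(0.0, 2 * np.pi)
            pos = pos + step_len * np.array([np.cos(heading), np.sin(heading)])
            rows.append((cid, t, pos[0], pos[1]))
    tracks = pd.DataFrame(rows, columns=["cell_id", "time_s", "x_um", "y_um"])
    ts = TrackSet(tracks, tuple(source), spec.stimulus_time)
    flags = pd.Series(responder, index=[f"cell{c:04d}" for c in range(spec.n_cells)])
    return GeneratedTracks(ts, flags)


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeGenSpec:
    """Genotype tables with identity groups and tunable between-group discordance."""

    n_loci: int = 1000
    sample_groups: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"lineA": ["A1", "A2"], "lineB": ["B1", "B2"]}
    )
    depth_mean: float = 30.0
    qual_range: tuple[float, float] = (50.0, 500.0)
    discordance_between_groups: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if not self.sample_groups:
            raise ValueError("at least one sample group required")
        for grp, members in self.sample_groups.items():
            if not list(members):
                raise ValueError(f"group {grp!r} is empty")
        _check_fraction("discordance_between_groups", self.discordance_between_groups)


@dataclass(frozen=True)
class GeneratedGenotypes:
    table: GenotypeTable
    groups: dict                     # hidden truth: group -> sample names


_GENOTYPES = np.array(["0/0", "0/1", "1/1"])
_GENOTYPE_PROBS = np.array([0.4, 0.4, 0.2])
_BASES = np.array(list("ACGT"))


def gen_genotypes(spec: GenotypeGenSpec) -> GeneratedGenotypes:
    """Draw a genotype table where same-group samples are exact copies.

    The first group carries base genotypes; every other group deviates at
    each locus independently with probability
    ``discordance_between_groups``, switching to a different genotype, so
    between-group identity is ``1 - discordance`` in expectation and
    within-group identity is exactly 1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_loci
    ref_idx = rng.integers(0, 4, n)
    alt_shift = rng.integers(1, 4, n)
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n + 1) * 100,
            "ref": _BASES[ref_idx],
            "alt": _BASES[(ref_idx + alt_shift) % 4],
            "qual": rng.uniform(*spec.qual_range, n),
        }
    )
    base = rng.choice(_GENOTYPES, size=n, p=_GENOTYPE_PROBS)
    group_gts: dict[str, np.ndarray] = {}
    for g, grp in enumerate(spec.sample_groups):
        if g == 0:
            group_gts[grp] = base
            continue
        gts = base.copy()
        flip = rng.random(n) < spec.discordance_between_groups
        for i in np.where(flip)[0]:
            alternatives = [gt for gt in _GENOTYPES if gt != base[i]]
            gts[i] = alternatives[rng.integers(0, len(alternatives))]
        group_gts[grp] = gts
    genotypes = {}
    depths = {}
    for grp, members in spec.sample_groups.items():
        for sample in members:
            genotypes[sample] = group_gts[grp]
            depths[sample] = rng.poisson(spec.depth_mean, n)
    gt_df = pd.DataFrame(genotypes, index=loci.index)
    dp_df = pd.DataFrame(depths, index=loci.index)
    table = GenotypeTable(loci, gt_df, dp_df)
    return GeneratedGenotypes(table, {g: list(m) for g, m in spec.sample_groups.items()})


# ---------------------------------------------------------------------------
# nuclei images


@dataclass
class NucleiImageSpec:
    """Two-channel images of non-overlapping elliptical nuclei.

    Pixel areas are drawn log-normal (``10**N(area_logmean, area_logsd)``);
    a ``f_dead`` fraction of nuclei is bright in the viability channel.
    Intensities are 16-bit with Gaussian noise.
    """

    image_size: tuple[int, int] = (512, 512)
    n_nuclei: int = 40
    area_logmean: float = 2.5            # log10 pixel area (~315 px)
    area_logsd: float = 0.12
    f_dead: float = 0.0
    background: float = 200.0
    foreground: float = 3000.0
    viability_background: float = 100.0
    viability_foreground: float = 2000.0
    noise_sd: float = 10.0
    max_tries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be nonnegative")
        _check_fraction("f_dead", self.f_dead)
        for level in (self.background, self.foreground,
                      self.viability_background, self.viability_foreground):
            if not 0 <= level < 2**16:
                raise ValueError("intensity levels must fit the 16-bit range")


@dataclass(frozen=True)
class GeneratedNucleiImage:
    nuclear: np.ndarray              # uint16 DNA channel
    viability: np.ndarray            # uint16 dead-cell stain channel
    truth: pd.DataFrame              # area_px, centroid_r, centroid_c, dead


def gen_nuclei_image(spec: NucleiImageSpec) -> GeneratedNucleiImage:
    """Render non-overlapping elliptical nuclei into a two-channel image pair.

    Placement uses rejection sampling with a 2-pixel exclusion margin so
    8-connected components never merge; raises :class:`GenerationError`
    when an object cannot be placed within ``max_tries`` attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    occupied = np.zeros((h, w), dtype=bool)
    nuclear = np.full((h, w), spec.background, dtype=float)
    viability = np.full((h, w), spec.viability_background, dtype=float)
    is_dead = rng.random(spec.n_nuclei) < spec.f_dead

    records = []
    for k in range(spec.n_nuclei):
        target_area = 10.0 ** rng.normal(spec.area_logmean, spec.area_logsd)
        ratio = rng.uniform(0.6, 0.95)
        a = np.sqrt(target_area / (np.pi * ratio))   # semi-major
        b = a * ratio                                 # semi-minor
        rotation = rng.uniform(0.0, np.pi)
        placed = False
        for _ in range(spec.max_tries):
            r = rng.uniform(a + 3, h - a - 3)
            c = rng.uniform(a + 3, w - a - 3)
            rr, cc = draw_ellipse(r, c, a, b, shape=(h, w), rotation=rotation)
            if rr.size == 0:
                continue
            # exclusion zone: slightly larger ellipse must be free
            rr2, cc2 = draw_ellipse(r, c, a + 2, b + 2, shape=(h, w), rotation=rotation)
            if occupied[rr2, cc2].any():
                continue
            occupied[rr2, cc2] = True
            nuclear[rr, cc] = spec.foreground
            if is_dead[k]:
                viability[rr, cc] = spec.viability_foreground
            records.append(
                {
                    "area_px": int(rr.size),
                    "centroid_r": float(rr.mean()),
                    "centroid_c": float(cc.mean()),
                    "dead": bool(is_dead[k]),
                }
            )
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place nucleus {k + 1}/{spec.n_nuclei} after "
                f"{spec.max_tries} tries; reduce n_nuclei or area"
            )
    if spec.noise_sd > 0:
        nuclear += rng.normal(0.0, spec.noise_sd, (h, w))
        viability += rng.normal(0.0, spec.noise_sd, (h, w))
    nuclear = np.clip(nuclear, 0, 2**16 - 1).astype(np.uint16)
    viability = np.clip(viability, 0, 2**16 - 1).astype(np.uint16)
    truth = pd.DataFrame(records, columns=["area_px", "centroid_r", "centroid_c", "dead"])
    return GeneratedNucleiImage(nuclear, viability, truth)
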