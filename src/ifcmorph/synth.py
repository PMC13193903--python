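"""Synthetic brightfield-like single-sperm image generator.

Emulates the statistical structure of an imaging-flow-cytometry acquisition
so every downstream stage (QC, sampling, training, evaluation) is testable
without real data:

* 10 categories — 8 morphology classes plus residual MULTI / DEBRIS frames;
* a bulls -> ejaculates -> files -> images hierarchy with multiplicative
  bull- and ejaculate-level random effects on morphometry, so records within
  a bull are statistically dependent;
* controllable breed / condition domain shifts (morphometry offsets,
  illumination gradient, noise level, contrast, class mixture).

The renderer is deliberately minimal geometry — head = filled ellipse with
edge darkening, midpiece = thick segment, tail = curved polyline, droplets =
bright discs, debris = irregular blobs, multiplet = two overlapping cells —
chosen so the 10 classes are separable yet confusable under noise (the
CTM/AT and TEH/IHS pairs share most of their geometry on purpose).

Nothing here attempts photorealism or optics simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .classes import (
    CLASS_ORDER,
    DEFECT_TO_CLASS,
    DefectSet,
    MorphClass,
    assign_label,
    defects_for_class,
)

# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class CellParams:
    """Parametric stand-in for real sperm morphometry, in pixels at 40x-like
    scale on the default 96 px canvas."""

    head_length_px: float = 19.0
    head_width_px: float = 10.0
    midpiece_length_px: float = 14.0
    tail_length_px: float = 42.0
    tail_curvature: float = 0.15
    droplet_radius_px: float = 3.0
    droplet_position: float = 0.5  # fraction along midpiece, 0 = at head
    orientation: float = 0.0  # degrees
    intensity_contrast: float = 0.55  # dimensionless, fraction of 255

    def __post_init__(self) -> None:
        for name in (
            "head_length_px",
            "head_width_px",
            "midpiece_length_px",
            "tail_length_px",
            "droplet_radius_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.droplet_position <= 1.0:
            raise ValueError("droplet_position must lie in [0, 1]")


#: CellParams fields carried as manifest columns
PARAM_COLUMNS = [f.name for f in dataclasses.fields(CellParams)]

#: default class mixtures; cryopreservation raises coiled/bent-tail rates
_FRESH_MIXTURE = {
    MorphClass.NM: 0.45, MorphClass.IHS: 0.07, MorphClass.TEH: 0.06,
    MorphClass.AM: 0.06, MorphClass.AT: 0.08, MorphClass.PCD: 0.05,
    MorphClass.DCD: 0.05, MorphClass.CTM: 0.08, MorphClass.MULTI: 0.05,
    MorphClass.DEBRIS: 0.05,
}
_FROZEN_MIXTURE = {
    MorphClass.NM: 0.40, MorphClass.IHS: 0.07, MorphClass.TEH: 0.06,
    MorphClass.AM: 0.06, MorphClass.AT: 0.09, MorphClass.PCD: 0.04,
    MorphClass.DCD: 0.04, MorphClass.CTM: 0.12, MorphClass.MULTI: 0.06,
    MorphClass.DEBRIS: 0.06,
}

BREEDS = ("KW", "SIM", "AUL")
CONDITIONS = ("fresh", "frozen")


def _mixture_vector(m: dict[MorphClass, float]) -> np.ndarray:
    return np.array([m[c] for c in CLASS_ORDER], dtype=float)


@dataclass(frozen=True)
class DomainParams:
    """One acquisition domain = breed x condition, with its shift knobs."""

    breed: str = "KW"
    condition: str = "fresh"
    season: str = "spring"
    morphometry_shift: dict = field(default_factory=dict)
    illumination_gradient: float = 0.0
    noise_sd: float = 6.0
    class_mixture: np.ndarray = field(
        default_factory=lambda: _mixture_vector(_FRESH_MIXTURE)
    )

    def __post_init__(self) -> None:
        mix = np.asarray(self.class_mixture, dtype=float)
        if mix.shape != (len(CLASS_ORDER),):
            raise ValueError(f"class_mixture must have {len(CLASS_ORDER)} entries")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1 within 1e-9")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "class_mixture", mix)


def default_domains(shift_scale: float = 1.0) -> list[DomainParams]:
    """The six breed x condition domains with default shifts.

    Frozen preparation multiplies noise by 1.5 and contrast by 0.85 and
    shifts the class mixture toward coiled/bent tails; breeds differ by
    +-10 % morphometry offsets. ``shift_scale`` scales all offsets relative
    to the baseline (0 = identical domains, for ablation runs).
    """
    s = shift_scale
    breed_shift = {
        "KW": {},
        "SIM": {"head_length_px": 1 + 0.10 * s, "head_width_px": 1 + 0.10 * s},
        "AUL": {"head_length_px": 1 - 0.10 * s, "tail_length_px": 1 - 0.10 * s},
    }
    doms = []
    for breed in BREEDS:
        for condition in CONDITIONS:
            shift = dict(breed_shift[breed])
            noise, grad = 6.0, 0.0
            mix = _mixture_vector(_FRESH_MIXTURE)
            if condition == "frozen":
                shift["intensity_contrast"] = 1 - 0.15 * s
                noise = 6.0 * (1 + 0.5 * s)
                grad = 0.06 * s
                frozen = _mixture_vector(_FROZEN_MIXTURE)
                mix = (1 - s) * mix + s * frozen
                mix = mix / mix.sum()
            doms.append(
                DomainParams(
                    breed=breed,
                    condition=condition,
                    season="summer" if condition == "frozen" else "spring",
                    morphometry_shift=shift,
                    illumination_gradient=grad,
                    noise_sd=noise,
                    class_mixture=mix,
                )
            )
    return doms


def domains_by_key(doms: list[DomainParams]) -> dict[tuple[str, str], DomainParams]:
    return {(d.breed, d.condition): d for d in doms}


@dataclass(frozen=True)
class HierarchySpec:
    """Acquisition design: bulls -> ejaculates -> files -> events.

    The default mirrors a six-bull collection with two fresh ejaculates
    (spring / fall) and one frozen ejaculate (summer) per bull, two files of
    50,000 events per sample — 1.8 million events in total.
    """

    n_bulls: int = 6
    ejaculates_per_bull: dict = field(
        default_factory=lambda: {"fresh": 2, "frozen": 1}
    )
    files_per_ejaculate: int = 2
    events_per_file: int = 50_000
    bull_effect_sd: float = 0.05
    ejaculate_effect_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_bulls, self.files_per_ejaculate, self.events_per_file]
        counts += list(self.ejaculates_per_bull.values())
        if any(c < 0 for c in counts):
            raise ValueError("all hierarchy counts must be >= 0")

    @property
    def total_events(self) -> int:
        per_bull = sum(self.ejaculates_per_bull.values())
        return (
            self.n_bulls * per_bull * self.files_per_ejaculate * self.events_per_file
        )


# ---------------------------------------------------------------------------
# defect sampling

# extras may only come from strictly lower-priority tags so the label
# round-trips through assign_label
_PRIORITY_TAGS = list(DEFECT_TO_CLASS)  # highest first
_EXTRA_PROB = 0.15


def sample_defects(cls: MorphClass, rng: np.random.Generator) -> DefectSet:
    """Draw a DefectSet whose assign_label is ``cls``.

    The defining defect is always present; lower-priority co-existing
    abnormalities are added independently with small probability, mirroring
    the frequent co-occurrence of defects on real cells.
    """
    if cls is MorphClass.DEBRIS or cls is MorphClass.MULTI or cls is MorphClass.NM:
        rng.random(len(_PRIORITY_TAGS))  # keep stream alignment across classes
        return defects_for_class(cls)
    base = defects_for_class(cls)
    (defining,) = base.defects
    idx = _PRIORITY_TAGS.index(defining)
    draws = rng.random(len(_PRIORITY_TAGS))
    extras = {
        tag
        for k, tag in enumerate(_PRIORITY_TAGS)
        if k > idx and draws[k] < _EXTRA_PROB
    }
    d = DefectSet(defects=frozenset({defining} | extras))
    assert assign_label(d) is cls
    return d


# ---------------------------------------------------------------------------
# morphometry sampling

_LENGTH_FIELDS = (
    "head_length_px",
    "head_width_px",
    "midpiece_length_px",
    "tail_length_px",
)
_LENGTH_CV = 0.08  # per-cell lognormal sigma on lengths


def sample_cell_params(
    cls: MorphClass,
    dom: DomainParams,
    rng: np.random.Generator,
    size_effect: float = 1.0,
) -> CellParams:
    """Draw one cell's morphometry under a domain and a cluster size effect."""
    base = CellParams()
    shift = dom.morphometry_shift
    vals: dict[str, float] = {}
    for name in _LENGTH_FIELDS:
        mean = getattr(base, name) * shift.get(name, 1.0) * size_effect
        vals[name] = mean * float(np.exp(rng.normal(0.0, _LENGTH_CV)))
    curv_mean = base.tail_curvature * shift.get("tail_curvature", 1.0)
    vals["tail_curvature"] = abs(float(rng.normal(curv_mean, 0.08)))
    vals["droplet_radius_px"] = base.droplet_radius_px * float(
        np.exp(rng.normal(0.0, 0.10))
    )
    if cls is MorphClass.PCD:
        vals["droplet_position"] = float(rng.uniform(0.08, 0.42))
    elif cls is MorphClass.DCD:
        vals["droplet_position"] = float(rng.uniform(0.58, 0.92))
    else:
        vals["droplet_position"] = float(rng.uniform(0.0, 1.0))
    vals["orientation"] = float(rng.uniform(0.0, 360.0))
    contrast = base.intensity_contrast * shift.get("intensity_contrast", 1.0)
    vals["intensity_contrast"] = contrast * float(np.exp(rng.normal(0.0, 0.05)))
    return CellParams(**vals)


# ---------------------------------------------------------------------------
# rendering

BACKGROUND = 218.0
DEFAULT_CANVAS = 96


def cell_layout(p: CellParams, canvas: int = DEFAULT_CANVAS) -> dict:
    """Geometric anchors shared by the renderer and by tests.

    Returns the neck point (head/midpiece junction), the unit axis vector
    ``u`` pointing from neck toward the head tip, the head centre, and the
    midpiece end point (tail junction), in (x, y) pixel coordinates.
    """
    theta = np.deg2rad(p.orientation)
    u = np.array([np.cos(theta), np.sin(theta)])
    total = p.head_length_px + p.midpiece_length_px + 0.65 * p.tail_length_px
    scale = min(1.0, 0.88 * canvas / total)
    hl = p.head_length_px * scale
    ml = p.midpiece_length_px * scale
    centre = np.array([canvas / 2.0, canvas / 2.0])
    # shift so the head end and tail extent are roughly balanced
    neck = centre + u * (0.5 * total * scale - hl)
    head_centre = neck + u * (hl / 2.0)
    mid_end = neck - u * ml
    return {
        "u": u,
        "neck": neck,
        "head_centre": head_centre,
        "mid_end": mid_end,
        "scale": scale,
        "head_len": hl,
        "head_wid": p.head_width_px * scale,
        "mid_len": ml,
        "tail_len": p.tail_length_px * scale,
    }


def _seg_dist(xx: np.ndarray, yy: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Distance of every pixel to segment a-b."""
    ab = b - a
    denom = float(ab @ ab) or 1.0
    t = ((xx - a[0]) * ab[0] + (yy - a[1]) * ab[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(xx - (a[0] + t * ab[0]), yy - (a[1] + t * ab[1]))


def _poly_dist(xx: np.ndarray, yy: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Min distance of every pixel to a dense polyline point set.

    Computed only inside the polyline's padded bounding box; everything
    outside is reported as inf (callers only threshold at ~1 px).
    """
    d = np.full(xx.shape, np.inf)
    pad = 4.0
    x0, y0 = np.floor(pts.min(axis=0) - pad).astype(int)
    x1, y1 = np.ceil(pts.max(axis=0) + pad).astype(int)
    h, w = xx.shape
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w - 1), min(y1, h - 1)
    if x1 < x0 or y1 < y0:
        return d
    sub_x = xx[y0 : y1 + 1, x0 : x1 + 1]
    sub_y = yy[y0 : y1 + 1, x0 : x1 + 1]
    dd = np.full(sub_x.shape, np.inf)
    for k in range(0, len(pts), 16):
        chunk = pts[k : k + 16]
        step = np.hypot(
            sub_x[..., None] - chunk[:, 0], sub_y[..., None] - chunk[:, 1]
        ).min(axis=-1)
        np.minimum(dd, step, out=dd)
    d[y0 : y1 + 1, x0 : x1 + 1] = dd
    return d


def _tail_points(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    curvature: float,
    coiled: bool,
    kinked: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integrate the tail path at ~1 px steps.

    Normal tails bend smoothly (quadratic heading); kinked (abnormal) tails
    add a sharp heading jump; coiled tails wind into a tight spiral near the
    midpiece junction, the hallmark of cryodamage.
    """
    n = max(int(length), 4)
    phi = float(np.arctan2(direction[1], direction[0]))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    pts = np.empty((n, 2))
    pos = start.astype(float).copy()
    if coiled:
        radius = rng.uniform(4.0, 6.5)
        for i in range(n):
            pts[i] = pos
            phi += sign / radius  # 1 px arc steps around the coil
            radius += 1.5 / n  # slow outward drift -> spiral, not circle
            pos += np.array([np.cos(phi), np.sin(phi)])
        return pts
    kink_at = int(rng.uniform(0.30, 0.60) * n) if kinked else -1
    bend = sign * curvature
    for i in range(n):
        pts[i] = pos
        if i == kink_at:
            phi += sign * np.deg2rad(rng.uniform(55.0, 95.0))
        phi += bend * (2.0 * i / n) / max(n, 1) * 8.0
        pos += np.array([np.cos(phi), np.sin(phi)])
    return pts


def _render_single_cell(
    img: np.ndarray,
    p: CellParams,
    d: DefectSet,
    rng: np.random.Generator,
    canvas: int,
    offset: np.ndarray | None = None,
) -> None:
    """Draw one cell onto ``img`` (darken-only compositing), in place."""
    lay = cell_layout(p, canvas)
    u, neck = lay["u"], lay["neck"]
    if offset is not None:
        neck = neck + offset
    head_c = neck + u * (lay["head_len"] / 2.0)
    mid_end = neck - u * lay["mid_len"]
    yy, xx = np.mgrid[0:canvas, 0:canvas].astype(float)
    dark = np.zeros_like(img)  # accumulated darkening, 0..1 of full contrast

    # --- head: rotated ellipse, darker toward the rim ---------------------
    a = lay["head_len"] / 2.0
    b = lay["head_wid"] / 2.0
    if "twisted_elongated_head" in d.defects:
        a, b = a * 1.55, b * 0.62
    dx, dy = xx - head_c[0], yy - head_c[1]
    ax = dx * u[0] + dy * u[1]  # along-axis coordinate
    px = -dx * u[1] + dy * u[0]  # perpendicular coordinate
    if "twisted_elongated_head" in d.defects:
        ax = ax + 0.18 * px * np.sign(ax)  # shear -> twisted look
    r2 = (ax / a) ** 2 + (px / b) ** 2
    if "irregular_head" in d.defects:
        ang = np.arctan2(px, ax)
        lobes = int(rng.integers(2, 5))
        phase = rng.uniform(0.0, 2 * np.pi)
        r2 = r2 * (1.0 + 0.35 * np.sin(lobes * ang + phase)) ** 2
    head = r2 <= 1.0
    dark[head] = np.maximum(dark[head], 0.55 + 0.45 * np.clip(r2[head], 0, 1))

    # --- midpiece: thick segment, thicker / bent when abnormal ------------
    w_mid = 1.6
    if "abnormal_midpiece" in d.defects:
        w_mid = 3.2
        elbow = neck - u * (lay["mid_len"] * 0.5) + np.array([-u[1], u[0]]) * 3.5
        dmid = np.minimum(
            _seg_dist(xx, yy, neck, elbow), _seg_dist(xx, yy, elbow, mid_end)
        )
    else:
        dmid = _seg_dist(xx, yy, neck, mid_end)
    mid = dmid <= w_mid
    dark[mid] = np.maximum(dark[mid], 0.62)

    # --- tail ---------------------------------------------------------------
    pts = _tail_points(
        mid_end,
        -u,
        lay["tail_len"],
        p.tail_curvature,
        coiled="coiled_tail_midpiece" in d.defects,
        kinked="abnormal_tail" in d.defects,
        rng=rng,
    )
    pts = np.clip(pts, 1.0, canvas - 2.0)
    dtail = _poly_dist(xx, yy, pts)
    tail = dtail <= 1.1
    dark[tail] = np.maximum(dark[tail], 0.50)

    np.minimum(img, BACKGROUND - 255.0 * p.intensity_contrast * dark, out=img)

    # --- cytoplasmic droplet: bright disc on the midpiece -------------------
    if "proximal_droplet" in d.defects or "distal_droplet" in d.defects:
        frac = p.droplet_position
        centre_d = neck - u * (frac * lay["mid_len"])
        rr = np.hypot(xx - centre_d[0], yy - centre_d[1])
        disc = rr <= p.droplet_radius_px * lay["scale"]
        img[disc] = np.maximum(img[disc], 250.0)


def _render_debris(
    img: np.ndarray, rng: np.random.Generator, canvas: int
) -> None:
    """1-4 irregular dark blobs, no cell."""
    yy, xx = np.mgrid[0:canvas, 0:canvas].astype(float)
    for _ in range(int(rng.integers(1, 5))):
        cx, cy = rng.uniform(0.2 * canvas, 0.8 * canvas, size=2)
        ra = rng.uniform(2.0, 6.0)
        rb = ra * rng.uniform(0.5, 1.0)
        th = rng.uniform(0.0, np.pi)
        dx, dy = xx - cx, yy - cy
        ax = dx * np.cos(th) + dy * np.sin(th)
        px = -dx * np.sin(th) + dy * np.cos(th)
        ang = np.arctan2(px, ax)
        r2 = ((ax / ra) ** 2 + (px / rb) ** 2) * (
            1.0 + 0.4 * np.sin(3 * ang + rng.uniform(0, 2 * np.pi))
        ) ** 2
        blob = r2 <= 1.0
        img[blob] = np.minimum(img[blob], BACKGROUND - rng.uniform(90.0, 140.0))


def render_cell_image(
    p: CellParams,
    d: DefectSet,
    dom: DomainParams,
    rng: np.random.Generator,
    canvas: int = DEFAULT_CANVAS,
) -> np.ndarray:
    """Render one frame (uint8 grayscale) from morphometry + defects."""
    img = np.full((canvas, canvas), BACKGROUND, dtype=float)
    if d.debris:
        _render_debris(img, rng, canvas)
    elif d.multiplet:
        _render_single_cell(img, p, d, rng, canvas)
        second = sample_cell_params(MorphClass.NM, dom, rng)
        off_ang = rng.uniform(0.0, 2 * np.pi)
        off = rng.uniform(14.0, 26.0) * np.array([np.cos(off_ang), np.sin(off_ang)])
        _render_single_cell(img, second, DefectSet(), rng, canvas, offset=off)
    else:
        _render_single_cell(img, p, d, rng, canvas)
    img = gaussian_filter(img, sigma=0.7)
    if dom.illumination_gradient:
        grad = (np.arange(canvas) - canvas / 2.0) / canvas
        img = img * (1.0 + dom.illumination_gradient * grad[None, :])
    img = img + rng.normal(0.0, dom.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_cell(
    cls: MorphClass | str,
    dom: DomainParams | None = None,
    rng_seed: int = 0,
    canvas: int = DEFAULT_CANVAS,
    size_effect: float = 1.0,
) -> tuple[np.ndarray, DefectSet]:
    """Generate one labeled frame: (uint8 grayscale image, DefectSet).

    Deterministic given (cls, dom, rng_seed). The returned DefectSet maps
    back to ``cls`` under :func:`assign_label`.
    """
    cls = MorphClass(cls)
    dom = dom or DomainParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 11]))
    d = sample_defects(cls, rng)
    p = sample_cell_params(cls, dom, rng, size_effect=size_effect)
    img = render_cell_image(p, d, dom, rng, canvas=canvas)
    return img, d


# ---------------------------------------------------------------------------
# hierarchical dataset generation

MANIFEST_META_COLUMNS = [
    "image_id",
    "path",
    "bull_id",
    "breed",
    "condition",
    "season",
    "ejaculate_id",
    "file_id",
    "label",
]


def _cluster_effect(seed: int, tag: int, index: int, sd: float) -> float:
    rng = np.random.default_rng(np.random.SeedSequence([seed, tag, index]))
    return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0


def generate_dataset(
    h: HierarchySpec | None = None,
    doms: list[DomainParams] | None = None,
    include_params: bool = True,
) -> pd.DataFrame:
    """Generate the manifest for a full acquisition design.

    Metadata-level only: no pixels are rendered here. Each row carries the
    hierarchy ids, the true class label drawn from the domain's class
    mixture, and the cell's morphometry (CellParams columns) already
    perturbed by bull- and ejaculate-level random effects. Images are
    rendered lazily from rows by :func:`render_record` (or written to disk
    by :func:`write_images`), bit-reproducibly from the stored seeds.

    ``include_params=False`` skips the morphometry draws and yields a lean
    ids+labels manifest; use it when only the acquisition design (row
    counts, hierarchy, class mixture) matters.
    """
    h = h or HierarchySpec()
    doms = doms if doms is not None else default_domains()
    dom_map = domains_by_key(doms)
    breeds = list(dict.fromkeys(d.breed for d in doms))
    if not breeds:
        raise ValueError("need at least one domain")
    base = CellParams()
    parts: list[dict] = []
    for b in range(h.n_bulls):
        breed = breeds[b % len(breeds)]
        bull_id = f"B{b:02d}"
        bull_eff = _cluster_effect(h.seed, 101, b, h.bull_effect_sd)
        j = 0
        for condition in ("fresh", "frozen"):
            n_ej = int(h.ejaculates_per_bull.get(condition, 0))
            for k in range(n_ej):
                if (breed, condition) not in dom_map:
                    raise KeyError(f"no DomainParams for {(breed, condition)}")
                dom = dom_map[(breed, condition)]
                season = (
                    "summer" if condition == "frozen"
                    else ("spring", "fall")[k % 2]
                )
                ej_eff = _cluster_effect(
                    h.seed, 202, b * 16 + j, h.ejaculate_effect_sd
                )
                size_eff = bull_eff * ej_eff
                for f in range(h.files_per_ejaculate):
                    parts.append(
                        _generate_file(
                            h, base, dom, bull_id, breed, condition, season,
                            b, j, f, size_eff, include_params,
                        )
                    )
                j += 1
    return _assemble_manifest(parts, h.seed, include_params)


def _assemble_manifest(
    parts: list[dict], seed: int, include_params: bool
) -> pd.DataFrame:
    """Concatenate per-file column dicts into one manifest DataFrame.

    String metadata become pandas Categoricals built from repeat codes and
    columns are assembled in final order, which keeps multi-million-row
    manifests cheap to build and hold.
    """
    param_cols = PARAM_COLUMNS if include_params else []
    order = MANIFEST_META_COLUMNS + param_cols + [
        "root_seed", "file_uid", "event_index",
    ]
    str_cols = {
        "bull_id", "breed", "condition", "season", "ejaculate_id", "file_id",
    }
    if not parts:
        out = {c: pd.Series([], dtype=np.float64) for c in order}
        for c in ("image_id", "root_seed", "file_uid", "event_index"):
            out[c] = pd.Series([], dtype=np.int64)
        for c in str_cols | {"path", "label"}:
            out[c] = pd.Series([], dtype=object)
        return pd.DataFrame({c: out[c] for c in order})
    n_total = sum(len(p["image_id"]) for p in parts)
    out = {}
    for c in order:
        if c in str_cols:
            levels = list(dict.fromkeys(p[c] for p in parts))
            lut = {v: i for i, v in enumerate(levels)}
            codes = np.concatenate(
                [
                    np.full(len(p["image_id"]), lut[p[c]], dtype=np.int32)
                    for p in parts
                ]
            )
            out[c] = pd.Categorical.from_codes(codes, categories=levels)
        elif c == "label":
            out[c] = pd.Categorical.from_codes(
                np.concatenate([p["label_codes"] for p in parts]).astype(
                    np.int32
                ),
                categories=[cl.value for cl in CLASS_ORDER],
            )
        elif c == "path":
            out[c] = pd.Categorical.from_codes(
                np.zeros(n_total, dtype=np.int32), categories=[""]
            )
        elif c == "root_seed":
            out[c] = np.full(n_total, seed, dtype=np.int64)
        else:
            out[c] = np.concatenate([p[c] for p in parts])
    return pd.DataFrame(out, copy=False)


def _generate_file(
    h: HierarchySpec,
    base: CellParams,
    dom: DomainParams,
    bull_id: str,
    breed: str,
    condition: str,
    season: str,
    b: int,
    j: int,
    f: int,
    size_eff: float,
    include_params: bool = True,
) -> dict:
    """Vectorized draw of one acquisition file's rows (column dict)."""
    n = h.events_per_file
    file_uid = (b * 16 + j) * 8 + f
    rng = np.random.default_rng(np.random.SeedSequence([h.seed, 3, file_uid]))
    label_codes = rng.choice(len(CLASS_ORDER), size=n, p=dom.class_mixture)
    event_index = np.arange(n, dtype=np.int64)
    cols: dict = {
        "image_id": np.int64(file_uid) * 1_000_000 + event_index,
        "label_codes": label_codes,
        "bull_id": bull_id,
        "breed": breed,
        "condition": condition,
        "season": season,
        "ejaculate_id": f"{bull_id}E{j}",
        "file_id": f"{bull_id}E{j}F{f}",
        "file_uid": np.full(n, file_uid, dtype=np.int64),
        "event_index": event_index,
    }
    if not include_params:
        return cols
    shift = dom.morphometry_shift
    for name in _LENGTH_FIELDS:
        mean = getattr(base, name) * shift.get(name, 1.0) * size_eff
        cols[name] = mean * np.exp(rng.normal(0.0, _LENGTH_CV, size=n))
    curv_mean = base.tail_curvature * shift.get("tail_curvature", 1.0)
    cols["tail_curvature"] = np.abs(rng.normal(curv_mean, 0.08, size=n))
    cols["droplet_radius_px"] = base.droplet_radius_px * np.exp(
        rng.normal(0.0, 0.10, size=n)
    )
    pos = rng.uniform(0.0, 1.0, size=n)
    pcd = label_codes == CLASS_ORDER.index(MorphClass.PCD)
    dcd = label_codes == CLASS_ORDER.index(MorphClass.DCD)
    pos[pcd] = 0.08 + 0.34 * rng.uniform(size=int(pcd.sum()))
    pos[dcd] = 0.58 + 0.34 * rng.uniform(size=int(dcd.sum()))
    cols["droplet_position"] = pos
    cols["orientation"] = rng.uniform(0.0, 360.0, size=n)
    contrast = base.intensity_contrast * shift.get("intensity_contrast", 1.0)
    cols["intensity_contrast"] = contrast * np.exp(rng.normal(0.0, 0.05, size=n))
    return cols


def params_from_row(row) -> CellParams:
    return CellParams(**{name: float(row[name]) for name in PARAM_COLUMNS})


def render_record(
    row,
    doms: list[DomainParams] | dict | None = None,
    canvas: int = DEFAULT_CANVAS,
) -> tuple[np.ndarray, DefectSet]:
    """Render one manifest row's frame, bit-reproducibly from stored seeds."""
    dom_map = (
        doms if isinstance(doms, dict)
        else domains_by_key(doms if doms is not None else default_domains())
    )
    dom = dom_map[(row["breed"], row["condition"])]
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(row["root_seed"]), 7, int(row["file_uid"]), int(row["event_index"])]
        )
    )
    cls = MorphClass(row["label"])
    d = sample_defects(cls, rng)
    p = params_from_row(row)
    img = render_cell_image(p, d, dom, rng, canvas=canvas)
    return img, d


def write_images(
    manifest: pd.DataFrame,
    out_dir,
    doms: list[DomainParams] | None = None,
    canvas: int = DEFAULT_CANVAS,
) -> pd.DataFrame:
    """Render every row to an 8-bit grayscale PNG; returns manifest with paths."""
    import imageio.v3 as iio
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dom_map = domains_by_key(doms if doms is not None else default_domains())
    paths = []
    for _, row in manifest.iterrows():
        img, _ = render_record(row, dom_map, canvas=canvas)
        path = out_dir / f"{int(row['image_id'])}.png"
        iio.imwrite(path, img)
        paths.append(str(path))
    out = manifest.copy()
    out["path"] = paths
    return out
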