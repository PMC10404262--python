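"""Seeded synthetic multi-domain cerebellum-like phantoms.

The phantom emulates, at desk scale, the structural and statistical features
that make infant cerebellum tissue segmentation hard:

* a folded, recursively branched tree of white matter (the arbor vitae),
* a thin gray-matter layer wrapped around the white-matter tree,
* a CSF shell around the gray matter,
* per-domain tissue intensity distributions whose GM/WM contrast collapses
  along an "age-descending" series of domains (emulating the loss of tissue
  contrast in younger infants) while noise grows,
* partial-volume blur and additive noise,
* optional injected topological defects ("hole" and "handle") that mimic the
  characteristic errors of automated segmentations.

Every generator is a pure function of its arguments and a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .types import BACKGROUND, CSF, GM, WM, LabelVolume

# canonical age-descending domain names mirroring the propagation chain
DEFAULT_DOMAIN_NAMES = ("24m", "18m", "12m", "9m", "6m", "0-3m")

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class PhantomSizingError(ValueError):
    """Requested phantom shape cannot contain the requested tree depth."""


@dataclass
class DomainSpec:
    """Per-domain tissue intensity model for the two-channel phantom.

    ``means`` and ``sds`` are (2, 4) arrays indexed [channel, tissue code]
    (channel 0 = T1w-like, channel 1 = T2w-like) in arbitrary intensity
    units. ``t2_inverted`` records that the T2w-like channel inverts the
    CSF/WM intensity ordering relative to the T1w-like channel, as real
    T2-weighted MRI does.
    """

    domain_id: str
    means: np.ndarray
    sds: np.ndarray
    noise_sigma: float = 5.0
    blur_sigma: float = 0.8
    t2_inverted: bool = True
    noise_model: str = "gaussian"  # or "rician"

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != (2, 4) or self.sds.shape != (2, 4):
            raise ValueError("means and sds must have shape (2, 4)")
        if np.any(self.sds <= 0):
            raise ValueError("all tissue standard deviations must be > 0")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sigma and blur_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def to_dict(self) -> dict:
        return {
            "domain_id": self.domain_id,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "noise_sigma": self.noise_sigma,
            "blur_sigma": self.blur_sigma,
            "t2_inverted": self.t2_inverted,
            "noise_model": self.noise_model,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainSpec":
        return cls(
            domain_id=d["domain_id"],
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            noise_sigma=float(d["noise_sigma"]),
            blur_sigma=float(d["blur_sigma"]),
            t2_inverted=bool(d["t2_inverted"]),
            noise_model=d.get("noise_model", "gaussian"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def default_base_spec(domain_id: str = "24m") -> DomainSpec:
    """High-contrast base domain emulating 24-month tissue intensities.

    Channel 0 (T1w-like): WM bright, GM intermediate, CSF dark.
    Channel 1 (T2w-like): CSF bright, GM intermediate, WM dark.
    """
    means = np.array(
        [
            [0.0, 30.0, 90.0, 140.0],  # T1w-like: bg, CSF, GM, WM
            [0.0, 160.0, 90.0, 60.0],  # T2w-like
        ]
    )
    sds = np.array(
        [
            [2.0, 8.0, 10.0, 10.0],
            [2.0, 10.0, 10.0, 8.0],
        ]
    )
    return DomainSpec(domain_id=domain_id, means=means, sds=sds)


def contrast_index(spec: DomainSpec, channel: int = 0) -> float:
    """GM/WM contrast-to-noise index on one channel.

    ``|mean_GM - mean_WM| / sqrt(pooled tissue variance + noise variance)``;
    a scalar summary of how separable the two tissue histograms are.
    """
    gap = abs(spec.means[channel, GM] - spec.means[channel, WM])
    pooled = 0.5 * (spec.sds[channel, GM] ** 2 + spec.sds[channel, WM] ** 2)
    return float(gap / math.sqrt(pooled + spec.noise_sigma**2))


def make_domain_series(
    base: DomainSpec,
    n_domains: int = 6,
    contrast_decay: float = 0.3,
    noise_growth: float = 0.1,
    invert_final: bool = True,
) -> list[DomainSpec]:
    """Age-descending series of domain specs with collapsing GM/WM contrast.

    Domain 0 is ``base``; each successive domain shrinks the GM-WM mean gap
    by ``contrast_decay`` (the gap magnitude decays as
    ``(1 - contrast_decay)**k``) on both channels and scales the additive
    noise by ``(1 + noise_growth)`` per step, so the GM/WM contrast index is
    strictly decreasing along the series. With ``invert_final`` the last
    domain's (smallest) gap additionally flips sign on both channels,
    emulating the isointense-to-inverted myelination contrast of the
    youngest infant scans: unmyelinated WM reads darker than GM on
    T1w-like images and brighter on T2w-like ones. CSF, being water, keeps
    its base-domain contrast at every age.
    """
    if n_domains < 2:
        raise ValueError("n_domains must be >= 2")
    if not (0.0 < contrast_decay < 1.0):
        raise ValueError("contrast_decay must lie strictly in (0, 1)")
    if noise_growth < 0:
        raise ValueError("noise_growth must be >= 0")

    names = list(DEFAULT_DOMAIN_NAMES[:n_domains])
    while len(names) < n_domains:
        names.append(f"dom{len(names)}")
    names[0] = base.domain_id

    series = [replace(base, domain_id=names[0])]
    keep = 1.0 - contrast_decay
    for k in range(1, n_domains):
        factor = keep**k
        if invert_final and k == n_domains - 1:
            factor = -factor
        means = base.means.copy()
        for ch in range(2):
            mid = 0.5 * (base.means[ch, GM] + base.means[ch, WM])
            for t in (GM, WM):
                means[ch, t] = mid + (base.means[ch, t] - mid) * factor
        series.append(
            replace(
                base,
                domain_id=names[k],
                means=means,
                noise_sigma=base.noise_sigma * (1.0 + noise_growth) ** k,
            )
        )
    return series


def _ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dz**2 + dy**2 + dx**2 <= radius**2 + 1e-9
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def _stamp(mask: np.ndarray, points: np.ndarray, radius: int) -> None:
    offs = _ball_offsets(radius)
    shape = np.array(mask.shape)
    for p in points:
        vox = np.clip(np.round(p + offs).astype(int), 0, shape - 1)
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True


def _random_rotation(direction: np.ndarray, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate a unit vector by ``angle`` around a random orthogonal axis."""
    d = direction / np.linalg.norm(direction)
    # random vector not parallel to d
    while True:
        v = rng.standard_normal(3)
        v -= v.dot(d) * d
        n = np.linalg.norm(v)
        if n > 1e-6:
            v /= n
            break
    return d * math.cos(angle) + v * math.sin(angle)


def make_label_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    branch_depth: int = 3,
    gm_thickness: int = 2,
    seed: int = 0,
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8),
    csf_thickness: int = 2,
) -> LabelVolume:
    """Tissue label phantom with a recursively branched white-matter tree.

    The WM core is carved as a trunk that forks into ``branch_depth`` levels
    of child branches of shrinking length and radius (a desk-scale analogue
    of the folded arbor vitae), producing a single 26-connected WM component.
    GM is the shell of Euclidean thickness ``gm_thickness`` around WM, CSF a
    further shell of ``csf_thickness``, and the remainder background.
    """
    shape = tuple(int(s) for s in shape)
    if branch_depth < 1:
        raise ValueError("branch_depth must be >= 1")
    if gm_thickness < 1:
        raise ValueError("gm_thickness must be >= 1")
    if min(shape) < 32:
        raise PhantomSizingError(f"shape {shape} too small; need >= 32 per axis")
    trunk_len = min(shape) / 3.5
    if trunk_len * 0.65 ** (branch_depth - 1) < 2.0:
        raise PhantomSizingError(
            f"shape {shape} too small to contain {branch_depth} branch levels"
        )

    rng = np.random.default_rng(seed)
    wm = np.zeros(shape, dtype=bool)
    margin = gm_thickness + csf_thickness + 2
    lo = np.full(3, margin, dtype=float)
    hi = np.array(shape, dtype=float) - 1 - margin

    def carve(pos: np.ndarray, direction: np.ndarray, length: float, radius: int, depth: int) -> np.ndarray:
        n_steps = max(2, int(round(length)))
        pts = []
        p = pos.copy()
        for _ in range(n_steps):
            step = direction + 0.15 * rng.standard_normal(3)  # gentle meander
            step /= np.linalg.norm(step)
            p = np.clip(p + step, lo, hi)
            pts.append(p.copy())
        _stamp(wm, np.array(pts), radius)
        end = p
        if depth > 1:
            n_children = int(rng.integers(2, 4))
            for _ in range(n_children):
                angle = rng.uniform(0.5, 0.9)  # ~30-50 degrees
                child_dir = _random_rotation(direction, angle, rng)
                carve(end, child_dir, length * 0.65, max(1, radius - 1), depth - 1)
        return end

    start = np.array(
        [margin + 1.0, shape[1] / 2.0, shape[2] / 2.0], dtype=float
    )
    trunk_dir = np.array([1.0, 0.0, 0.0])
    radius0 = 3  # trunk radius; children shrink toward 1-voxel twigs
    carve(start, trunk_dir, trunk_len, radius0, branch_depth)

    # the recursive carving is connected by construction; keep the largest
    # component defensively in case clipping at the margins split a branch
    comp, n_comp = ndimage.label(wm, structure=_STRUCT26)
    if n_comp > 1:
        sizes = ndimage.sum_labels(wm, comp, index=np.arange(1, n_comp + 1))
        wm = comp == (1 + int(np.argmax(sizes)))

    dist = ndimage.distance_transform_edt(~wm)
    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    labels[(dist > 0) & (dist <= gm_thickness)] = GM
    labels[(dist > gm_thickness) & (dist <= gm_thickness + csf_thickness)] = CSF
    labels[wm] = WM

    # enforce the shell property: any GM voxel fully surrounded by GM in its
    # 26-neighborhood is relabeled CSF (a trapped pocket between branches)
    while True:
        gm_mask = labels == GM
        interior = ndimage.minimum_filter(
            gm_mask.astype(np.uint8), footprint=_STRUCT26, mode="constant", cval=0
        ).astype(bool)
        if not interior.any():
            break
        labels[interior] = CSF

    return LabelVolume(labels, spacing=spacing)


@dataclass
class DefectInjection:
    """Result of topology-defect injection: altered labels plus bookkeeping."""

    labels: LabelVolume
    mask: np.ndarray
    kinds_placed: list[str] = field(default_factory=list)
    n_requested: int = 0
    n_clipped: int = 0

    @property
    def n_placed(self) -> int:
        return len(self.kinds_placed)

    def __iter__(self):
        # allow ``labels, mask = inject_topology_defects(...)``
        return iter((self.labels, self.mask))


def inject_topology_defects(
    labels: LabelVolume,
    n_defects: int,
    kinds: tuple[str, ...] = ("hole", "handle"),
    seed: int = 0,
    min_separation: int = 8,
) -> DefectInjection:
    """Inject "hole" and "handle" topology defects into a label phantom.

    A *hole* relabels a small ball of interior WM as GM (a gap punched into
    the tree); a *handle* grows a spurious WM bridge from the WM surface
    across the surrounding GM/CSF gap. Defect sites are kept at least
    ``min_separation`` voxels apart so the returned binary mask has one
    connected component per placed defect. If fewer sites are available than
    requested, placement is clipped and the shortfall is reported in
    ``n_clipped``. Voxels outside the returned mask are never altered.
    """
    if n_defects < 0:
        raise ValueError("n_defects must be >= 0")
    for k in kinds:
        if k not in ("hole", "handle"):
            raise ValueError(f"unknown defect kind {k!r}")

    rng = np.random.default_rng(seed)
    vox = labels.voxels.copy()
    mask = np.zeros(vox.shape, dtype=bool)
    result = DefectInjection(
        labels=LabelVolume(vox, spacing=labels.spacing),
        mask=mask,
        n_requested=n_defects,
    )
    if n_defects == 0:
        return result

    wm = vox == WM
    # hole sites: WM voxels whose radius-2 ball is entirely WM
    interior = ndimage.binary_erosion(wm, structure=_ball_mask(2), border_value=0)
    # handle sites: WM surface voxels (face-adjacent to non-WM)
    surface = wm & ~ndimage.binary_erosion(wm, structure=_face_struct(), border_value=0)

    placed_centers: list[np.ndarray] = []

    def far_enough(c: np.ndarray) -> bool:
        return all(np.linalg.norm(c - p) >= min_separation for p in placed_centers)

    for _ in range(n_defects):
        kind = kinds[rng.integers(len(kinds))] if len(kinds) > 1 else kinds[0]
        sites = np.argwhere(interior if kind == "hole" else surface)
        if sites.size == 0:
            result.n_clipped += 1
            continue
        order = rng.permutation(len(sites))
        chosen = None
        for idx in order[: min(len(order), 200)]:
            c = sites[idx].astype(float)
            if far_enough(c):
                chosen = sites[idx]
                break
        if chosen is None:
            result.n_clipped += 1
            continue
        if kind == "hole":
            radius = int(rng.integers(1, 3))
            offs = _ball_offsets(radius)
            pts = np.clip(chosen + offs, 0, np.array(vox.shape) - 1)
            sel = np.zeros(vox.shape, dtype=bool)
            sel[pts[:, 0], pts[:, 1], pts[:, 2]] = True
            sel &= wm  # only formerly-WM voxels change
            vox[sel] = GM
            mask |= sel
        else:
            changed = _grow_handle(vox, wm, chosen, rng)
            if changed is None:
                result.n_clipped += 1
                continue
            vox[changed] = WM
            mask |= changed
        placed_centers.append(chosen.astype(float))
        result.kinds_placed.append(kind)

    result.labels = LabelVolume(vox, spacing=labels.spacing)
    return result


def _grow_handle(
    vox: np.ndarray, wm: np.ndarray, start: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """Walk outward from a WM surface voxel, converting a short path to WM."""
    shape = np.array(vox.shape)
    for _ in range(10):  # retry directions
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        path = []
        p = start.astype(float)
        for _ in range(int(rng.integers(4, 7))):
            p = p + d
            q = np.round(p).astype(int)
            if np.any(q < 0) or np.any(q >= shape):
                break
            if not wm[tuple(q)]:
                path.append(q)
        if len(path) >= 3:
            changed = np.zeros(vox.shape, dtype=bool)
            for q in path:
                changed[tuple(q)] = True
            return changed
    return None


def _ball_mask(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    return (dz**2 + dy**2 + dx**2) <= radius**2 + 1e-9


def _face_struct() -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1)


def render_intensities(labels: LabelVolume, spec: DomainSpec, seed: int = 0):
    """Render a two-channel intensity volume from a label phantom.

    Per-voxel intensities are drawn from the tissue's per-channel normal
    distribution, blurred with a Gaussian of width ``blur_sigma`` voxels
    (partial-volume emulation), then corrupted with additive noise of scale
    ``noise_sigma`` (Gaussian, or Rician if the spec selects it).
    """
    from .types import IntensityVolume  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    vox = labels.voxels
    channels = []
    for ch in range(2):
        img = spec.means[ch][vox] + spec.sds[ch][vox] * rng.standard_normal(vox.shape)
        if spec.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, spec.blur_sigma)
        if spec.noise_sigma > 0:
            if spec.noise_model == "rician":
                n1 = spec.noise_sigma * rng.standard_normal(vox.shape)
                n2 = spec.noise_sigma * rng.standard_normal(vox.shape)
                img = np.sqrt((img + n1) ** 2 + n2**2)
            else:
                img = img + spec.noise_sigma * rng.standard_normal(vox.shape)
        channels.append(img.astype(np.float32))
    return IntensityVolume(
        np.stack(channels, axis=0), spacing=labels.spacing, domain_id=spec.domain_id
    )


def histogram_overlap(
    intensity, labels: LabelVolume, channel: int = 0, n_bins: int = 64
) -> float:
    """Overlap coefficient of the GM and WM intensity histograms on one channel.

    ``sum(min(p_GM, p_WM))`` over shared bins — 0 for perfectly separated
    tissue distributions, 1 for identical ones.
    """
    img = intensity.voxels[channel]
    gm_vals = img[labels.voxels == GM]
    wm_vals = img[labels.voxels == WM]
    if gm_vals.size == 0 or wm_vals.size == 0:
        raise ValueError("phantom lacks GM or WM voxels")
    lo = min(gm_vals.min(), wm_vals.min())
    hi = max(gm_vals.max(), wm_vals.max())
    bins = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(gm_vals, bins=bins, density=False)
    q, _ = np.histogram(wm_vals, bins=bins, density=False)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.minimum(p, q).sum())
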