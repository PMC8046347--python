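"""Semi-automated intervertebral disc segmentation on sagittal multi-echo MRI.

The chain follows the published raw-intensity recipe.  On the second echo
(highest disc/bone contrast) a 1x15 vertical median image is computed; the
pixel column with the most pixels at least 100 units above the median image
locates the spine centre.  Local minima below 150 units along that column
seed the vertebral endplates, which are tracked anteriorly/posteriorly
(step accepted when >=3 of the pixel's 8-neighbours are below 150 units),
then optionally refined by a minimum-cost graph search (Dijkstra) between
support points, with gradient-direction deviation and grey value as costs.
Anterior/posterior borders come from the first column (scanning outward
from the centre) where the echo-averaged image differs from the median
image by >=80 units.  Paired endplate contours are filled and clipped to
give one mask per disc.

Operator support points can be supplied from file; by default they are
placed automatically (equally spaced along the tracked contours) so the
pipeline runs unattended.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .io import EchoStack

__all__ = [
    "SegmentationParams",
    "SliceImages",
    "SliceSegmentation",
    "DiscSegmentation",
    "SegmentationError",
    "SpineNotFoundError",
    "DiscBorderError",
    "MaskOverlapError",
    "vertical_median_filter",
    "locate_spine_centre",
    "detect_endplate_seeds",
    "track_endplate_contours",
    "dijkstra_boundary",
    "propagate_support_points",
    "find_ap_borders",
    "extract_disc_masks",
    "pair_disc_contours",
    "segment_slice",
    "segment_stack",
]


class SegmentationError(RuntimeError):
    pass


class SpineNotFoundError(SegmentationError):
    pass


class DiscBorderError(SegmentationError):
    pass


class MaskOverlapError(SegmentationError):
    pass


@dataclass
class SegmentationParams:
    """Tunable thresholds; defaults are the published raw-unit values."""

    median_height: int = 15  # 1 px wide x 15 rows
    diff_threshold_locate: float = 100.0
    endplate_intensity_threshold: float = 150.0
    neighbor_count_min: int = 3
    ap_border_threshold: float = 80.0
    support_points_per_disc: int = 8
    cost_weight_gradient: float = 0.5
    cost_weight_grey: float = 0.5
    gradient_sigma: float = 1.0  # px, Gaussian pre-smoothing for gradients
    track_row_step: int = 2  # contour may move +-2 rows per column
    min_contour_length: int = 5  # px; shorter tracked contours are discarded
    search_radius: int = 5  # px, support-point propagation
    propagation_lambda: float = 0.5
    disc_gap_mean_min: float = 500.0  # 2nd-echo mean between contours that marks a disc gap
    dijkstra_window_pad: int | None = 8  # search window half-margin; None = whole image
    refine_with_graph_search: bool = True
    trim_dark_pixels: bool = True  # drop sub-threshold (endplate) pixels from filled masks

    def __post_init__(self) -> None:
        if self.median_height % 2 == 0:
            raise ValueError("median window height must be odd")
        for name in ("diff_threshold_locate", "endplate_intensity_threshold", "ap_border_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SliceImages:
    """Intermediate images for one slice (identical dimensions)."""

    second_echo: np.ndarray
    averaged: np.ndarray
    median: np.ndarray
    locate_mask: np.ndarray  # (second_echo - median) >= locate threshold


@dataclass
class SliceSegmentation:
    slice_index: int
    images: SliceImages
    centre_column: int
    seeds: list[int]
    contours: list[np.ndarray]  # (n, 2) arrays of (row, col), sorted by col
    masks: list[np.ndarray]  # one boolean mask per disc, cephalad to caudad
    borders: list[tuple[int, int]]  # per-disc (anterior_x, posterior_x)


@dataclass
class DiscSegmentation:
    """Per-slice disc masks with cephalad-to-caudad level labels."""

    slices: list[SliceSegmentation]
    levels: list[str] = field(default_factory=list)

    def mask(self, slice_index: int, level: str) -> np.ndarray:
        return self.slices[slice_index].masks[self.levels.index(level)]


# ---------------------------------------------------------------------------
# elementary operations


def vertical_median_filter(image: np.ndarray, height: int = 15) -> np.ndarray:
    """Median over a 1-px-wide, ``height``-row vertical window (reflected
    padding at the borders)."""
    image = np.asarray(image, dtype=float)
    if image.shape[0] < height:
        raise ValueError(f"image has {image.shape[0]} rows < median window height {height}")
    return ndimage.median_filter(image, size=(height, 1), mode="reflect")


def locate_spine_centre(image: np.ndarray, median_image: np.ndarray,
                        params: SegmentationParams | None = None) -> int:
    """Column with the most pixels >= ``diff_threshold_locate`` units above
    the median image (signed difference); ties go to the smallest column."""
    params = params or SegmentationParams()
    image = np.asarray(image, dtype=float)
    if image.shape != np.shape(median_image):
        raise ValueError("image and median_image must have the same shape")
    counts = ((image - median_image) >= params.diff_threshold_locate).sum(axis=0)
    if counts.max() == 0:
        raise SpineNotFoundError("no spinal structure detected")
    return int(np.argmax(counts))


def detect_endplate_seeds(image: np.ndarray, centre_column: int,
                          params: SegmentationParams | None = None) -> list[int]:
    """Rows of strict local minima below the endplate threshold along the
    centre column; a plateau reports its (lower-)middle row."""
    params = params or SegmentationParams()
    profile = np.asarray(image, dtype=float)[:, centre_column]
    thr = params.endplate_intensity_threshold
    seeds: list[int] = []
    i, n = 0, profile.size
    while i < n:
        j = i
        while j + 1 < n and profile[j + 1] == profile[i]:
            j += 1
        left_higher = i > 0 and profile[i - 1] > profile[i]
        right_higher = j < n - 1 and profile[j + 1] > profile[i]
        if left_higher and right_higher and profile[i] < thr:
            seeds.append((i + j) // 2)
        i = j + 1
    return seeds


def _dark_neighbor_counts(image: np.ndarray, threshold: float) -> np.ndarray:
    dark = (np.asarray(image, dtype=float) < threshold).astype(np.int8)
    kernel = np.ones((3, 3), dtype=np.int8)
    kernel[1, 1] = 0
    return ndimage.convolve(dark, kernel, mode="constant", cval=0)


def track_endplate_contours(image: np.ndarray, seeds: list[int],
                            params: SegmentationParams | None = None,
                            centre_column: int | None = None,
                            col_limits: tuple[int, int] | None = None) -> list[np.ndarray]:
    """Grow an endplate contour anteriorly and posteriorly from each seed.

    A step to the adjacent column may move at most ``track_row_step`` rows
    and is accepted only if the target pixel has at least
    ``neighbor_count_min`` 8-neighbours below the endplate threshold;
    among admissible targets the darkest wins (ties: smallest row change,
    then upper row).  Contours shorter than ``min_contour_length`` are
    discarded with a warning.
    """
    params = params or SegmentationParams()
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if centre_column is None:
        centre_column = w // 2
    lo, hi = col_limits if col_limits is not None else (0, w - 1)
    ncount = _dark_neighbor_counts(image, params.endplate_intensity_threshold)
    contours = []
    for seed in seeds:
        points = {centre_column: seed}
        for step in (-1, 1):
            y, col = seed, centre_column
            while lo <= col + step <= hi:
                col += step
                rows = np.arange(max(y - params.track_row_step, 0),
                                 min(y + params.track_row_step, h - 1) + 1)
                ok = rows[ncount[rows, col] >= params.neighbor_count_min]
                if ok.size == 0:
                    break
                order = np.lexsort((ok, np.abs(ok - y), image[ok, col]))
                y = int(ok[order[0]])
                points[col] = y
        cols = np.array(sorted(points))
        contour = np.column_stack([np.array([points[c] for c in cols]), cols])
        if contour.shape[0] < params.min_contour_length:
            warnings.warn(f"discarding contour from seed row {seed}: only {contour.shape[0]} px")
            continue
        contours.append(contour)
    return contours


def _node_costs(image: np.ndarray, p: np.ndarray, q: np.ndarray,
                params: SegmentationParams) -> np.ndarray:
    """Per-pixel cost in [0,1]: gradient-direction deviation from the mean
    support-point gradient, plus normalised grey value."""
    smooth = ndimage.gaussian_filter(np.asarray(image, dtype=float), params.gradient_sigma)
    gy, gx = np.gradient(smooth)
    mag = np.hypot(gx, gy)

    def unit_grad(pt):
        g = np.array([gx[pt[0], pt[1]], gy[pt[0], pt[1]]])
        n = np.hypot(*g)
        return g / n if n > 0 else g

    ref = unit_grad(p) + unit_grad(q)
    ref_norm = np.hypot(*ref)
    if ref_norm > 0:
        ref = ref / ref_norm
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(mag > 0, (gx * ref[0] + gy * ref[1]) / np.where(mag > 0, mag, 1.0), 0.0)
        grad_cost = 0.5 * (1.0 - cos)
    else:
        grad_cost = np.full(image.shape, 0.5)

    lo, hi = float(image.min()), float(image.max())
    grey_cost = (image - lo) / (hi - lo) if hi > lo else np.zeros(image.shape)
    cost = params.cost_weight_gradient * grad_cost + params.cost_weight_grey * grey_cost
    return np.clip(cost, 0.0, None)  # guard float rounding of the cosine term


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _min_cost_path(cost: np.ndarray, src: tuple[int, int], dst: tuple[int, int]) -> tuple[np.ndarray, float]:
    """Minimum-cost 8-connected path; edge weight = cost of the target node."""
    h, w = cost.shape
    idx = lambda r, c: r * w + c
    rows_i, cols_j, data = [], [], []
    for dr, dc in _OFFSETS:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        rows_i.append((rr * w + cc).ravel())
        cols_j.append(((rr + dr) * w + (cc + dc)).ravel())
        data.append(cost[rr + dr, cc + dc].ravel())
    graph = coo_matrix(
        (np.concatenate(data), (np.concatenate(rows_i), np.concatenate(cols_j))),
        shape=(h * w, h * w),
    ).tocsr()
    dist, pred = _csgraph_dijkstra(graph, directed=True, indices=idx(*src), return_predecessors=True)
    target = idx(*dst)
    if not np.isfinite(dist[target]):
        raise SegmentationError("support points are not connected")
    path = [target]
    while path[-1] != idx(*src):
        path.append(int(pred[path[-1]]))
    path = np.array(path[::-1])
    return np.column_stack([path // w, path % w]), float(dist[target])


def dijkstra_boundary(averaged_image: np.ndarray, support_points: np.ndarray,
                      params: SegmentationParams | None = None) -> tuple[np.ndarray, float]:
    """Minimum-cost 8-connected boundary through consecutive support points.

    Returns the concatenated (row, col) path and its total cost (sum over
    entered nodes).  With ``dijkstra_window_pad`` set, each pair is routed
    inside its padded bounding box for speed; ``None`` searches the whole
    image.
    """
    params = params or SegmentationParams()
    image = np.asarray(averaged_image, dtype=float)
    pts = np.atleast_2d(np.asarray(support_points, dtype=int))
    if pts.shape[0] < 2:
        raise ValueError("need at least two support points")
    h, w = image.shape
    if (pts[:, 0] < 0).any() or (pts[:, 0] >= h).any() or (pts[:, 1] < 0).any() or (pts[:, 1] >= w).any():
        raise ValueError("support points outside image")

    segments = []
    total = 0.0
    for p, q in zip(pts[:-1], pts[1:]):
        cost = _node_costs(image, p, q, params)
        if params.dijkstra_window_pad is None:
            win = (slice(0, h), slice(0, w))
        else:
            pad = params.dijkstra_window_pad
            win = (
                slice(max(0, min(p[0], q[0]) - pad), min(h, max(p[0], q[0]) + pad + 1)),
                slice(max(0, min(p[1], q[1]) - pad), min(w, max(p[1], q[1]) + pad + 1)),
            )
        sub = cost[win]
        src = (p[0] - win[0].start, p[1] - win[1].start)
        dst = (q[0] - win[0].start, q[1] - win[1].start)
        path, c = _min_cost_path(sub, src, dst)
        path = path + [win[0].start, win[1].start]
        if segments:
            path = path[1:]
        segments.append(path)
        total += c
    return np.vstack(segments), total


def propagate_support_points(source_image: np.ndarray, adjacent_image: np.ndarray,
                             points: np.ndarray, search_radius: int = 5,
                             lam: float = 0.5) -> np.ndarray:
    """Carry support points to an adjacent slice.

    For each point the pixel within ``search_radius`` of the current
    position minimising ``|dGrey| + lam*|dGradMag| + lam*dGradAngle`` (angle
    normalised to [0,1]) is chosen; candidates are visited by increasing
    displacement so an exact feature match keeps the point in place.  If the
    neighbourhood carries no gradients at all the point stays put with a
    warning.
    """
    src = np.asarray(source_image, dtype=float)
    adj = np.asarray(adjacent_image, dtype=float)
    if src.shape != adj.shape:
        raise ValueError("slices must have the same shape")
    gy_s, gx_s = np.gradient(ndimage.gaussian_filter(src, 1.0))
    gy_a, gx_a = np.gradient(ndimage.gaussian_filter(adj, 1.0))
    mag_s, mag_a = np.hypot(gx_s, gy_s), np.hypot(gx_a, gy_a)
    ang_s, ang_a = np.arctan2(gy_s, gx_s), np.arctan2(gy_a, gx_a)
    h, w = adj.shape

    offs = [(dr, dc) for dr in range(-search_radius, search_radius + 1)
            for dc in range(-search_radius, search_radius + 1)
            if dr * dr + dc * dc <= search_radius * search_radius]
    offs.sort(key=lambda o: (o[0] * o[0] + o[1] * o[1], o[0], o[1]))

    out = []
    for r, c in np.atleast_2d(np.asarray(points, dtype=int)):
        best, best_cost, any_grad = (r, c), np.inf, False
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w):
                continue
            if mag_a[rr, cc] > 0:
                any_grad = True
            dang = abs(ang_s[r, c] - ang_a[rr, cc])
            dang = min(dang, 2 * np.pi - dang) / np.pi
            cost = abs(src[r, c] - adj[rr, cc]) + lam * abs(mag_s[r, c] - mag_a[rr, cc]) + lam * dang
            if cost < best_cost - 1e-12:
                best, best_cost = (rr, cc), cost
        if not any_grad:
            warnings.warn(f"no gradients near ({r}, {c}) in adjacent slice; point kept in place")
            best = (r, c)
        out.append(best)
    return np.asarray(out, dtype=int)


@dataclass
class ApBorders:
    """Per-row anterior/posterior border columns for one row span."""

    rows: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray
    degenerate: np.ndarray  # rows where the centre column itself crossed the threshold


def find_ap_borders(averaged_image: np.ndarray, median_image: np.ndarray,
                    centre_column: int, row_spans: list[tuple[int, int]],
                    params: SegmentationParams | None = None) -> list[ApBorders]:
    """First column each side of the centre where |averaged - median| >=
    the 80-unit border threshold; unresolved rows inherit the nearest
    resolved row of their span."""
    params = params or SegmentationParams()
    diff = np.abs(np.asarray(averaged_image, dtype=float) - np.asarray(median_image, dtype=float))
    hit = diff >= params.ap_border_threshold
    h, w = hit.shape
    if not 0 <= centre_column < w:
        raise ValueError("centre column outside image")
    out = []
    for y0, y1 in row_spans:
        rows = np.arange(max(y0, 0), min(y1, h - 1) + 1)
        ant = np.full(rows.size, -1)
        post = np.full(rows.size, -1)
        degen = np.zeros(rows.size, dtype=bool)
        for k, y in enumerate(rows):
            if hit[y, centre_column]:
                ant[k] = post[k] = centre_column
                degen[k] = True
                continue
            left = np.nonzero(hit[y, : centre_column + 1][::-1])[0]
            right = np.nonzero(hit[y, centre_column:])[0]
            if left.size:
                ant[k] = centre_column - left[0]
            if right.size:
                post[k] = centre_column + right[0]
        for arr in (ant, post):
            resolved = np.nonzero(arr >= 0)[0]
            if resolved.size == 0:
                raise DiscBorderError(f"no anterior/posterior border found in rows {y0}-{y1}")
            missing = np.nonzero(arr < 0)[0]
            if missing.size:
                nearest = resolved[np.argmin(np.abs(resolved[None, :] - missing[:, None]), axis=1)]
                arr[missing] = arr[nearest]
        if degen.any():
            warnings.warn("anterior/posterior border degenerate at the centre column for some rows")
        out.append(ApBorders(rows=rows, anterior=ant, posterior=post, degenerate=degen))
    return out


def _contour_row_map(contour: np.ndarray) -> dict[int, float]:
    """col -> mean row for an 8-connected or tracked contour."""
    cols = contour[:, 1]
    rows = contour[:, 0].astype(float)
    out: dict[int, float] = {}
    for c in np.unique(cols):
        out[int(c)] = rows[cols == c].mean()
    return out


def pair_disc_contours(contours: list[np.ndarray], second_echo: np.ndarray,
                       params: SegmentationParams | None = None,
                       centre_column: int | None = None):
    """Classify consecutive contour gaps as disc or non-disc.

    Contours are sorted cephalad to caudad; the gap between a consecutive
    pair is a disc when the second-echo intensity between them (sampled
    around the centre column) exceeds ``disc_gap_mean_min`` - discs are far
    brighter than vertebral bodies or background on the second echo.
    Returns the list of (upper, lower) contour pairs.
    """
    params = params or SegmentationParams()
    image = np.asarray(second_echo, dtype=float)
    h, w = image.shape
    if centre_column is None:
        centre_column = w // 2
    ordered = sorted(contours, key=lambda c: c[:, 0].mean())
    pairs = []
    cols_probe = np.arange(max(0, centre_column - 5), min(w, centre_column + 6))
    for upper, lower in zip(ordered[:-1], ordered[1:]):
        um, lm = _contour_row_map(upper), _contour_row_map(lower)
        vals = []
        for c in cols_probe:
            if int(c) in um and int(c) in lm:
                a, b = int(round(um[int(c)])) + 1, int(round(lm[int(c)]))
                if b > a:
                    vals.append(image[a:b, c].mean())
        if vals and float(np.mean(vals)) >= params.disc_gap_mean_min:
            pairs.append((upper, lower))
    return pairs


def extract_disc_masks(pairs, borders, shape: tuple[int, int],
                       image: np.ndarray | None = None,
                       params: SegmentationParams | None = None) -> list[np.ndarray]:
    """Fill each (superior, inferior) contour pair into a disc mask.

    ``borders`` gives one (anterior_x, posterior_x) pair per disc; the fill
    covers rows strictly between the contours over the columns where both
    are defined, clipped to the borders, with holes filled.  When the
    second-echo ``image`` is supplied, sub-threshold (endplate-dark) pixels
    are trimmed from the fill and the largest connected component kept.
    Overlapping masks abort: an overlap means contour pairing failed.
    """
    params = params or SegmentationParams()
    masks = []
    occupancy = np.zeros(shape, dtype=np.int16)
    for (upper, lower), (ant, post) in zip(pairs, borders):
        um, lm = _contour_row_map(upper), _contour_row_map(lower)
        mask = np.zeros(shape, dtype=bool)
        for c in sorted(set(um) & set(lm)):
            if not ant <= c <= post:
                continue
            a = int(np.floor(um[c])) + 1
            b = int(np.ceil(lm[c]))  # exclusive: boundary pixels stay out
            if b > a:
                mask[a:b, c] = True
        if not mask.any():
            warnings.warn("contour pair produced an empty mask; skipped")
            continue
        mask = ndimage.binary_fill_holes(mask)
        if image is not None and params.trim_dark_pixels:
            mask &= np.asarray(image, dtype=float) >= params.endplate_intensity_threshold
            lab, n = ndimage.label(mask)
            if n > 1:
                sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
                mask = lab == (1 + int(np.argmax(sizes)))
        occupancy += mask
        masks.append(mask)
    if (occupancy > 1).any():
        raise MaskOverlapError("filled disc regions overlap; contour detection failed")
    return masks


# ---------------------------------------------------------------------------
# per-slice and per-stack drivers


def _auto_support_points(contour: np.ndarray, n_points: int) -> np.ndarray:
    """Equally spaced points along a tracked contour (automatic stand-in for
    the operator's manual marks)."""
    cols = np.unique(contour[:, 1])
    take = np.unique(np.linspace(0, cols.size - 1, num=min(n_points, cols.size)).round().astype(int))
    rm = _contour_row_map(contour)
    return np.column_stack([[int(round(rm[int(c)])) for c in cols[take]], cols[take]])


def _refine_contour(averaged: np.ndarray, contour: np.ndarray,
                    params: SegmentationParams,
                    points: np.ndarray | None = None) -> np.ndarray:
    pts = points if points is not None else _auto_support_points(contour, params.support_points_per_disc)
    if pts.shape[0] < 2:
        return contour
    path, _ = dijkstra_boundary(averaged, pts, params)
    rm = _contour_row_map(path)
    cols = np.array(sorted(rm))
    return np.column_stack([[int(round(rm[int(c)])) for c in cols], cols])


def segment_slice(slice_data: np.ndarray, params: SegmentationParams | None = None,
                  slice_index: int = 0,
                  support_points: dict | None = None) -> SliceSegmentation:
    """Segment the discs of one slice ``(n_echoes, H, W)``."""
    params = params or SegmentationParams()
    second = np.asarray(slice_data[1], dtype=float)
    averaged = np.asarray(slice_data, dtype=float).mean(axis=0)
    median = vertical_median_filter(second, params.median_height)
    centre = locate_spine_centre(second, median, params)
    locate_mask = (second - median) >= params.diff_threshold_locate
    images = SliceImages(second_echo=second, averaged=averaged, median=median, locate_mask=locate_mask)

    seeds = detect_endplate_seeds(second, centre, params)
    if not seeds:
        raise SegmentationError("no endplate seed points below the intensity threshold")
    contours = track_endplate_contours(second, seeds, params, centre_column=centre)
    if params.refine_with_graph_search:
        refined = []
        for i, contour in enumerate(contours):
            pts = None
            if support_points is not None and i in support_points:
                pts = support_points[i]
            refined.append(_refine_contour(averaged, contour, params, points=pts))
        contours = refined

    pairs = pair_disc_contours(contours, second, params, centre_column=centre)
    if not pairs:
        raise SegmentationError("no disc-like contour pairs found")

    # anterior/posterior borders from the vertebral-body rows adjacent to
    # each disc (the body interior keeps |averaged - median| under the
    # threshold; the first crossing marks the spine wall).  Rows are taken
    # well clear of the endplates, and the per-disc border is the outermost
    # hit: spurious early crossings can only occur inside the spine, never
    # beyond the wall.
    margin = 6
    depth = 6
    h = second.shape[0]
    spans, span_of_disc = [], []
    for upper, lower in pairs:
        um, lm = _contour_row_map(upper), _contour_row_map(lower)
        top = int(round(um.get(centre, upper[:, 0].mean())))
        bot = int(round(lm.get(centre, lower[:, 0].mean())))
        above = (max(0, top - margin - depth), max(0, top - margin))
        below = (min(h - 1, bot + margin), min(h - 1, bot + margin + depth))
        span_of_disc.append((len(spans), len(spans) + 1))
        spans.extend([above, below])
    ap = find_ap_borders(averaged, median, centre, spans, params)
    borders = []
    for ia, ib in span_of_disc:
        ant = int(np.min(np.concatenate([ap[ia].anterior, ap[ib].anterior])))
        post = int(np.max(np.concatenate([ap[ia].posterior, ap[ib].posterior])))
        borders.append((ant, post))

    masks = extract_disc_masks(pairs, borders, second.shape, image=second, params=params)
    return SliceSegmentation(
        slice_index=slice_index,
        images=images,
        centre_column=centre,
        seeds=seeds,
        contours=contours,
        masks=masks,
        borders=borders,
    )


def segment_stack(stack: EchoStack, params: SegmentationParams | None = None,
                  levels: list[str] | None = None,
                  support_points: dict | None = None) -> DiscSegmentation:
    """Segment every slice of a session.

    The central (third) slice is processed first, as in the original
    protocol; the remaining slices are processed independently with the
    same parameters.  ``support_points`` may map ``(slice, contour_index)``
    to operator-marked (row, col) arrays.
    """
    params = params or SegmentationParams()
    order = [2] + [s for s in range(stack.n_slices) if s != 2] if stack.n_slices >= 3 else list(range(stack.n_slices))
    results: dict[int, SliceSegmentation] = {}
    n_discs = None
    for s in order:
        sp = None
        if support_points is not None:
            sp = {i: pts for (sl, i), pts in support_points.items() if sl == s}
        seg = segment_slice(stack.data[s], params, slice_index=s, support_points=sp or None)
        if n_discs is None:
            n_discs = len(seg.masks)
        elif len(seg.masks) != n_discs:
            raise SegmentationError(
                f"slice {s} found {len(seg.masks)} discs, expected {n_discs}"
            )
        results[s] = seg
    slices = [results[s] for s in sorted(results)]
    if levels is None:
        from .phantom import DEFAULT_DISC_LEVELS

        levels = list(DEFAULT_DISC_LEVELS[-n_discs:]) if n_discs <= 6 else [f"D{i}" for i in range(n_discs)]
    if len(levels) != n_discs:
        raise SegmentationError(f"{n_discs} discs found but {len(levels)} level labels supplied")
    return DiscSegmentation(slices=slices, levels=list(levels))
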