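"""Cohort-level model: fundus images in, group-difference statistics out.

:class:`VesselNetworkCohort` is built from a cohort manifest (image path or
array, optional precomputed mask, optional optic-disc coordinates, group
label) plus a :class:`RunConfig`; ``fit()`` runs the full per-image pipeline

    image -> vessel mask -> skeleton -> weighted graph -> feature samples
          -> fractal-dimension pair

and then the cohort comparison

    histograms on shared bins -> pairwise JS divergences -> IsoMap plane
          -> per-method group t statistics,

returning a :class:`CohortResults` whose ``summary()`` is the per-method
p-value table (one row per analysis and exponent pair, one column per group
pair).  Images on which a stage fails are recorded with their failure status
and excluded from cohort statistics, never silently dropped.
"""

from __future__ import annotations

import itertools
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import compare, features as nf, fractal, segmentation as seg, vessel_graph as vgm
from .errors import (
    CentralAssignmentError,
    DiscNotFound,
    FundusGraphError,
    GraphExtractionError,
    SegmentationFailure,
)
from .synthetic import SyntheticImage

__all__ = ["RunConfig", "ImageRecord", "VesselNetworkCohort", "CohortResults", "run_image", "run_cohort"]

logger = logging.getLogger("fundusgraph")

#: canonical analysis rows: (method, l, a)
CANONICAL_METHODS: tuple[tuple[str, float, float], ...] = (
    ("cndd", 1.0, -2.0),
    ("cndd", 1.0, 2.0),
    ("cmwd", 1.0, -2.0),
    ("wdd", 0.0, 1.0),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a cohort run depends on besides the manifest itself."""

    method_configs: tuple[tuple[str, float, float], ...] = CANONICAL_METHODS
    n_bins: int = 64
    isomap_k: int = 10
    spur_length: int = 3
    segmentation: seg.SegmentationParams = field(default_factory=seg.SegmentationParams)
    disc_confidence_threshold: float = 1.2
    fractal_scales: tuple[int, ...] | None = None  # None -> dyadic default
    calibrated_p: bool = True
    use_first_coordinate: bool = False
    allow_mixed_resolution: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        import yaml

        d = {
            "method_configs": [list(m) for m in self.method_configs],
            "n_bins": self.n_bins,
            "isomap_k": self.isomap_k,
            "spur_length": self.spur_length,
            "segmentation": vars(self.segmentation).copy(),
            "disc_confidence_threshold": self.disc_confidence_threshold,
            "fractal_scales": list(self.fractal_scales) if self.fractal_scales else None,
            "calibrated_p": self.calibrated_p,
            "use_first_coordinate": self.use_first_coordinate,
            "allow_mixed_resolution": self.allow_mixed_resolution,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = seg.SegmentationParams(**d["segmentation"])
        if d.get("method_configs"):
            d["method_configs"] = tuple(tuple(m) for m in d["method_configs"])
        if d.get("fractal_scales"):
            d["fractal_scales"] = tuple(d["fractal_scales"])
        return cls(**d)


@dataclass
class ImageRecord:
    """Per-image pipeline outcome."""

    id: str
    label: str
    status: str = "ok"  # ok | segmentation_failed | disc_not_found | central_failed | graph_failed
    detail: str = ""
    counts: nf.BasicCounts | None = None
    fd: fractal.FdPoint | None = None
    samples: dict[tuple[str, float, float], np.ndarray] = field(default_factory=dict)
    shape: tuple[int, int] | None = None
    runtime_s: float = 0.0


def _load_image(item: dict) -> np.ndarray | None:
    img = item.get("image")
    if img is None:
        return None
    if isinstance(img, (str, Path)):
        import imageio.v3 as iio

        return iio.imread(img)
    return np.asarray(img)


def _load_item_mask(item: dict) -> seg.VesselMask | None:
    m = item.get("mask")
    if m is None:
        return None
    if isinstance(m, seg.VesselMask):
        return m
    if isinstance(m, (str, Path)):
        return seg.load_mask(m)
    return seg.VesselMask(np.asarray(m, bool), source="manual")


def run_image(item: dict, config: RunConfig | None = None) -> ImageRecord:
    """Run the full per-image pipeline on one manifest item.

    ``item`` keys: ``id``, ``label``, and either ``image`` (path or RGB
    array) or ``mask`` (path, array or VesselMask; bypasses segmentation),
    plus optional ``disc`` = (row, col) and ``disc_radius`` which bypass
    optic-disc detection.  Any stage failure is recorded in ``status`` and
    downstream stages are skipped.
    """
    config = config or RunConfig()
    rec = ImageRecord(id=str(item.get("id", "")), label=str(item.get("label", "")))
    t0 = time.perf_counter()
    try:
        mask = _load_item_mask(item)
        image = _load_image(item)
        if mask is None:
            if image is None:
                raise ValueError(f"item {rec.id}: neither image nor mask supplied")
            enhanced = seg.enhance_contrast(image)
            mask = seg.segment_vessels(enhanced, config.segmentation)
        rec.shape = mask.data.shape

        if item.get("disc") is not None:
            disc = seg.OpticDisc(
                center=tuple(map(float, item["disc"])),
                radius=float(item.get("disc_radius") or 0.04 * min(mask.data.shape)),
            )
        else:
            disc = seg.locate_optic_disc(
                image if image is not None else mask.data.astype(float),
                mask,
                confidence_threshold=config.disc_confidence_threshold,
            )

        skel = vgm.skeletonize(mask.data)
        vg = vgm.extract_graph(skel, mask.data, spur_length=config.spur_length)
        vgm.estimate_widths(vg, mask.data, skel)
        vgm.assign_central_node(vg, disc)

        rec.counts = nf.basic_counts(vg)
        scales = np.asarray(config.fractal_scales) if config.fractal_scales else None
        rec.fd = fractal.fd_pair(mask.data, scales)

        for method, l, a in config.method_configs:
            vgm.apply_weights(vg, vgm.WeightConfig(l, a))
            if method == "wdd":
                rec.samples[(method, l, a)] = nf.wdd_samples(vg).values
            else:
                profile = nf.central_distances(vg)
                fn = nf.cndd_samples if method == "cndd" else nf.cmwd_samples
                rec.samples[(method, l, a)] = fn(profile).values
        rec.status = "ok"
    except SegmentationFailure as e:
        rec.status, rec.detail = "segmentation_failed", str(e)
    except DiscNotFound as e:
        rec.status, rec.detail = "disc_not_found", str(e)
    except CentralAssignmentError as e:
        rec.status, rec.detail = "central_failed", str(e)
    except GraphExtractionError as e:
        rec.status, rec.detail = "graph_failed", str(e)
    rec.runtime_s = time.perf_counter() - t0
    logger.info("image %s [%s]: %s (%.2fs)", rec.id, rec.label, rec.status, rec.runtime_s)
    return rec


class VesselNetworkCohort:
    """Model object: a labelled cohort of fundus images plus a run config.

    Build with :meth:`from_manifest` (CSV / DataFrame of paths and labels)
    or :meth:`from_images` (in-memory synthetic images); ``fit()`` runs the
    pipeline and returns a :class:`CohortResults`.
    """

    def __init__(self, items: Sequence[dict], config: RunConfig | None = None):
        if not items:
            raise ValueError("empty cohort")
        self.items = list(items)
        self.config = config or RunConfig()

    @classmethod
    def from_manifest(
        cls,
        manifest,
        config: RunConfig | None = None,
        root: str | Path | None = None,
        mask_column: str = "mask",
        disc_columns: tuple[str, str] = ("disc_row", "disc_col"),
    ) -> "VesselNetworkCohort":
        """Build from a manifest CSV/DataFrame with columns
        ``image``, ``label`` and optionally ``mask``, ``disc_row``, ``disc_col``."""
        df = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)
        base = Path(root) if root else None
        items = []
        for i, row in df.iterrows():
            item: dict[str, Any] = {
                "id": str(row.get("id", Path(str(row["image"])).stem if "image" in row else i)),
                "label": row["label"],
            }
            if "image" in df.columns and isinstance(row["image"], str) and row["image"]:
                p = Path(row["image"])
                item["image"] = str(base / p) if base and not p.is_absolute() else str(p)
            if mask_column in df.columns and isinstance(row[mask_column], str) and row[mask_column]:
                p = Path(row[mask_column])
                item["mask"] = str(base / p) if base and not p.is_absolute() else str(p)
            r, c = disc_columns
            if r in df.columns and c in df.columns and pd.notna(row[r]) and pd.notna(row[c]):
                item["disc"] = (float(row[r]), float(row[c]))
            items.append(item)
        return cls(items, config)

    @classmethod
    def from_images(
        cls,
        images: Sequence[SyntheticImage],
        config: RunConfig | None = None,
        use_true_masks: bool = False,
        use_true_disc: bool = False,
    ) -> "VesselNetworkCohort":
        """Build from in-memory synthetic images.

        ``use_true_masks`` / ``use_true_disc`` bypass segmentation and disc
        detection with the generator's ground truth (the manual-mask path).
        """
        items = []
        for i, img in enumerate(images):
            item: dict[str, Any] = {
                "id": f"synth_{i:03d}",
                "label": img.group_label or "unlabelled",
                "image": img.raster,
            }
            if use_true_masks:
                item["mask"] = seg.VesselMask(img.mask, source="manual")
            if use_true_disc:
                item["disc"] = img.disc_center
                item["disc_radius"] = img.disc_radius
            items.append(item)
        return cls(items, config)

    def fit(self) -> "CohortResults":
        cfg = self.config
        records = [run_image(item, cfg) for item in self.items]

        shapes = {r.shape for r in records if r.shape is not None}
        if len(shapes) > 1 and not cfg.allow_mixed_resolution:
            raise ValueError(
                f"mixed image resolutions in cohort ({sorted(shapes)}); pixel-unit "
                "features are resolution-dependent — supply a uniform-resolution "
                "manifest or set allow_mixed_resolution=True"
            )

        ok = [r for r in records if r.status == "ok"]
        labels = np.array([r.label for r in ok])
        pairs = list(itertools.combinations(sorted(set(labels.tolist())), 2))

        tests: list[dict] = []
        histograms: dict[tuple[str, float, float], compare.HistogramSet] = {}
        divergences: dict[tuple[str, float, float], compare.DivergenceMatrix] = {}
        embeddings: dict[tuple[str, float, float], compare.Embedding2D] = {}

        def add_test(analysis, l, a, pair, gt: compare.GroupTest):
            tests.append(
                {
                    "analysis": analysis,
                    "l": l,
                    "a": a,
                    "pair": f"{pair[0]} vs {pair[1]}",
                    "t": gt.t,
                    "p": gt.p,
                    "p_projected": gt.p_projected,
                    "note": gt.note,
                }
            )

        # distribution-based methods: histograms -> JSD -> IsoMap -> test
        for key in cfg.method_configs:
            method, l, a = key
            sample_sets = [r.samples[key] for r in ok if key in r.samples]
            if len(sample_sets) < 4:
                warnings.warn(f"too few usable images for {method}({l},{a}); skipped")
                continue
            try:
                edges = compare.common_bin_edges(sample_sets, cfg.n_bins)
            except ValueError as e:
                warnings.warn(f"{method}({l},{a}): {e}; skipped")
                continue
            probs = np.array([compare.to_histogram(s, edges) for s in sample_sets])
            hset = compare.HistogramSet(edges=edges, probabilities=probs, ids=[r.id for r in ok])
            histograms[key] = hset
            dmat = compare.divergence_matrix(hset)
            divergences[key] = dmat
            emb = compare.isomap_2d(dmat, cfg.isomap_k)
            embeddings[key] = emb
            name = {"cndd": "C-NDD", "cmwd": "CMWD", "wdd": "WDD"}[method]
            for pair in pairs:
                sel = np.isin(labels, pair)
                if min((labels[sel] == g).sum() for g in pair) < 2:
                    warnings.warn(f"{name}: fewer than 2 usable images in a group; test skipped")
                    continue
                gt = compare.group_separation(
                    emb.coords[sel],
                    labels[sel],
                    method=name,
                    calibrated=cfg.calibrated_p,
                    use_first_coordinate=cfg.use_first_coordinate,
                )
                add_test(name, l, a, pair, gt)

        # basic counts: plain pooled t-tests
        count_names = ["nodes", "links", "endpoints", "bifurcations"]
        count_rows = {
            n: np.array([getattr(r.counts, n) for r in ok], dtype=float) for n in count_names
        }
        pretty = {
            "nodes": "Nodes",
            "links": "Links",
            "endpoints": "Endpoints",
            "bifurcations": "Bifurcation points",
        }
        for n in count_names:
            for pair in pairs:
                a_vals = count_rows[n][labels == pair[0]]
                b_vals = count_rows[n][labels == pair[1]]
                if len(a_vals) < 2 or len(b_vals) < 2:
                    continue
                add_test(pretty[n], np.nan, np.nan, pair, compare.ttest2(a_vals, b_vals))

        # fractal plane: each axis separately, then the best direction
        fd_arr = np.array([[r.fd.d_skeleton, r.fd.d_raw] for r in ok])
        for pair in pairs:
            sel = np.isin(labels, pair)
            la, lb = (labels[sel] == pair[0]), (labels[sel] == pair[1])
            if la.sum() < 2 or lb.sum() < 2:
                continue
            sub = fd_arr[sel]
            add_test(
                "FD skeletonized", np.nan, np.nan, pair, compare.ttest2(sub[la, 0], sub[lb, 0])
            )
            add_test("FD raw", np.nan, np.nan, pair, compare.ttest2(sub[la, 1], sub[lb, 1]))
            add_test(
                "FD best direction",
                np.nan,
                np.nan,
                pair,
                compare.group_separation(sub, labels[sel], calibrated=cfg.calibrated_p),
            )

        return CohortResults(
            records=records,
            config=cfg,
            tests=pd.DataFrame(tests),
            histograms=histograms,
            divergences=divergences,
            embeddings=embeddings,
        )


@dataclass
class CohortResults:
    """Fitted cohort: per-image records, per-method statistics, embeddings."""

    records: list[ImageRecord]
    config: RunConfig
    tests: pd.DataFrame
    histograms: dict = field(default_factory=dict)
    divergences: dict = field(default_factory=dict)
    embeddings: dict = field(default_factory=dict)

    # -- per-image tables --------------------------------------------------
    @property
    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "label": [r.label for r in self.records],
                "status": [r.status for r in self.records],
                "detail": [r.detail for r in self.records],
                "runtime_s": [round(r.runtime_s, 3) for r in self.records],
            }
        )

    @property
    def n_usable(self) -> int:
        return sum(1 for r in self.records if r.status == "ok")

    @property
    def n_discarded(self) -> int:
        return len(self.records) - self.n_usable

    @property
    def feature_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            if r.status != "ok":
                continue
            row = {"id": r.id, "label": r.label, **r.counts.as_dict()}
            row["fd_skeleton"] = r.fd.d_skeleton
            row["fd_raw"] = r.fd.d_raw
            rows.append(row)
        return pd.DataFrame(rows)

    def samples_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for (method, l, a), vals in r.samples.items():
                for v in vals:
                    rows.append({"id": r.id, "method": method, "l": l, "a": a, "value": v})
        return pd.DataFrame(rows)

    # -- cohort-level ------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Per-method p-value table: one row per analysis, column per pair."""
        if self.tests.empty:
            return self.tests
        t = self.tests.copy()
        t["row"] = [
            f"{an} (l={l:g}, a={a:g})" if np.isfinite(l) else an
            for an, l, a in zip(t.analysis, t.l, t.a)
        ]
        out = t.pivot_table(index="row", columns="pair", values="p", sort=False)
        out.index.name = "analysis"
        return out.reset_index()

    def p_value(self, analysis: str, pair: str | None = None) -> float:
        sel = self.tests[self.tests.analysis == analysis]
        if pair is not None:
            sel = sel[sel.pair == pair]
        if sel.empty:
            raise KeyError(f"no test named {analysis!r}")
        return float(sel.iloc[0]["p"])

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "report_images.csv", index=False)
        self.feature_table.to_csv(out / "counts.csv", index=False)
        self.feature_table[["id", "label", "fd_skeleton", "fd_raw"]].to_csv(
            out / "fd.csv", index=False
        )
        self.samples_table().to_csv(out / "features.csv", index=False)
        self.tests.to_csv(out / "report.csv", index=False)
        for (method, l, a), dm in self.divergences.items():
            tag = f"{method}_l{l:g}_a{a:g}".replace("-", "m")
            pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).to_csv(
                out / f"jsd_{tag}.csv"
            )
        for (method, l, a), emb in self.embeddings.items():
            tag = f"{method}_l{l:g}_a{a:g}".replace("-", "m")
            pd.DataFrame(
                {"id": emb.ids, "x": emb.coords[:, 0], "y": emb.coords[:, 1]}
            ).to_csv(out / f"embedding_{tag}.csv", index=False)

    # -- plots -------------------------------------------------------------
    def plot_fractal_plane(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ft = self.feature_table
        for label, grp in ft.groupby("label"):
            ax.scatter(grp.fd_skeleton, grp.fd_raw, label=label, alpha=0.8)
        ax.set_xlabel("D (skeletonized)")
        ax.set_ylabel("D (raw mask)")
        ax.legend()
        return ax

    def plot_embedding(self, method_key, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        emb = self.embeddings[method_key]
        labels = {r.id: r.label for r in self.records}
        lab = np.array([labels[i] for i in emb.ids])
        for g in sorted(set(lab.tolist())):
            s = lab == g
            ax.scatter(emb.coords[s, 0], emb.coords[s, 1], label=g, alpha=0.8)
        ax.set_xlabel("IsoMap 1")
        ax.set_ylabel("IsoMap 2")
        ax.legend()
        return ax


def run_cohort(manifest, config: RunConfig | None = None, root=None) -> CohortResults:
    """Convenience: build a :class:`VesselNetworkCohort` from a manifest and fit."""
    return VesselNetworkCohort.from_manifest(manifest, config, root=root).fit()
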