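"""The end-to-end screening pipeline and untargeted feature finding.

Stage order is fixed: align -> detect -> fold isotopologues -> group
adducts -> remove artifacts -> blank subtract -> assign formulas (with
isotope verification and erroneous-formula filtering) -> MS2 library
screen -> metrics -> compositional groupings.  Every stage logs its
feature count and every removal carries a reason, so features are
conserved: retained + removed = detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .artifacts import blank_subtract, group_adducts, remove_artifacts
from .assign import Assignment, assign_feature
from .chem import ION_SPECIES, metrics
from .config import PipelineConfig
from .constants import ISOTOPE_SPACING
from .features import Feature
from .ms2 import LibraryEntry, MS2Spectrum, assign_confidence, search
from .peaks import EIC, MzWindow, Run, align_runs, detect_peaks, extract_eic
from .quant import group_composition, source_report

__all__ = ["find_features", "fold_isotopologues", "run_pipeline", "PipelineResult"]


def find_features(run: Run, config: PipelineConfig | None = None) -> list[Feature]:
    """Untargeted feature detection over all m/z in a centroided run.

    Centroids from all scans are pooled and clustered along m/z (a gap
    larger than the accurate-mass tolerance starts a new cluster); each
    cluster's EIC is screened with the S/N, minimum-intensity and
    consecutive-scan rules.  One Feature is emitted per detected
    chromatographic peak.
    """
    config = config or PipelineConfig()
    all_mz = np.concatenate([s.mz for s in run.scans]) if run.scans else np.empty(0)
    all_int = np.concatenate([s.intensity for s in run.scans])
    if all_mz.size == 0:
        return []
    order = np.argsort(all_mz, kind="stable")
    mz_sorted = all_mz[order]
    int_sorted = all_int[order]
    # cluster boundaries where the m/z gap exceeds the ppm tolerance
    gaps = np.diff(mz_sorted) > mz_sorted[:-1] * config.eic_ppm * 1e-6
    bounds = np.flatnonzero(gaps) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [mz_sorted.size]])
    features: list[Feature] = []
    fid = 0
    for a, b in zip(starts, ends):
        cluster_max = int_sorted[a:b].max()
        if cluster_max < config.min_intensity:
            continue
        lo = mz_sorted[a] * (1 - 0.1e-6)
        hi = mz_sorted[b - 1] * (1 + 0.1e-6) + 1e-9
        window = MzWindow(lo, hi, "accurate")
        eic = extract_eic(run, window)
        peaks = detect_peaks(
            eic,
            min_sn=config.min_sn,
            min_intensity=config.min_intensity,
            min_scans=config.min_scans,
        )
        w = int_sorted[a:b]
        mz_center = float(np.average(mz_sorted[a:b], weights=w))
        for p in peaks:
            features.append(
                Feature(
                    feature_id=f"{run.sample}:F{fid:05d}",
                    mz=mz_center,
                    rt=p.apex_rt,
                    area=p.area,
                    apex_intensity=p.apex_intensity,
                    sn=p.sn,
                    n_scans=p.n_scans,
                    sample=run.sample,
                    polarity=run.polarity,
                )
            )
            fid += 1
    features.sort(key=lambda f: (f.mz, f.rt))
    return features


def fold_isotopologues(
    features: list[Feature],
    mz_tol: float = 0.01,
    rt_tol: float = 0.05,
) -> tuple[list[Feature], list[dict]]:
    """Attach A+1/A+2 partner features to their parents and drop them.

    A feature is an isotopologue of a parent when it sits 1 or 2 times
    the 13C spacing above the parent m/z (within ``mz_tol`` Da),
    co-elutes within ``rt_tol`` min, and is less intense.  Observed
    intensities are recorded on the parent for the isotope check.
    """
    out = list(features)
    removed: set[str] = set()
    log: list[dict] = []
    by_mz = sorted(out, key=lambda f: f.mz)
    for parent in by_mz:
        if parent.feature_id in removed:
            continue
        parent.isotopes.setdefault("A", parent.apex_intensity)
        for k, key in ((1, "A1"), (2, "A2")):
            target = parent.mz + k * ISOTOPE_SPACING
            cands = [
                g
                for g in by_mz
                if g.feature_id != parent.feature_id
                and g.feature_id not in removed
                and abs(g.mz - target) <= mz_tol
                and abs(g.rt - parent.rt) <= rt_tol
                and g.apex_intensity < parent.apex_intensity
            ]
            if cands:
                iso = max(cands, key=lambda g: g.apex_intensity)
                parent.isotopes[key] = iso.apex_intensity
                removed.add(iso.feature_id)
                log.append(
                    {
                        "feature_id": iso.feature_id,
                        "reason": "isotopologue",
                        "parent_id": parent.feature_id,
                        "isotopologue": key,
                    }
                )
    return [f for f in out if f.feature_id not in removed], log


@dataclass
class PipelineResult:
    """Bundle of all pipeline outputs for one invocation."""

    features: pd.DataFrame
    assignments: list[Assignment]
    table: pd.DataFrame  # final per-compound table
    grouped: pd.DataFrame | None
    sources: pd.DataFrame | None
    removal_log: pd.DataFrame
    stage_counts: dict[str, int]
    config: PipelineConfig
    log_lines: list[str] = field(default_factory=list)


def run_pipeline(
    samples: list[Run],
    blanks: list[Run] | None = None,
    config: PipelineConfig | None = None,
    library: list[LibraryEntry] | None = None,
    ms2_spectra: dict[str, list[MS2Spectrum]] | None = None,
) -> PipelineResult:
    """Execute the full non-targeted workflow on one or more sample runs.

    ``blanks`` are solvent/procedural blank runs (matched by their
    ``role``); missing blanks downgrade to a logged warning.  ``library``
    enables MS2 identification for features with a query spectrum in
    ``ms2_spectra`` (keyed by sample name).  Deterministic for fixed
    inputs and config.
    """
    if not samples:
        raise ValueError("at least one sample run is required")
    config = config or PipelineConfig()
    for r in samples + (blanks or []):
        if r.polarity != config.polarity:
            raise ValueError(
                f"run {r.sample!r} polarity {r.polarity} != config {config.polarity}"
            )
    log: list[str] = [f"config: {config.to_dict()}"]
    counts: dict[str, int] = {}
    removal: list[dict] = []

    if config.align and len(samples) > 1:
        warps = align_runs(samples)
        for run, warp in zip(samples, warps):
            for s in run.scans:
                s.rt = float(warp(s.rt))
        log.append(
            "aligned runs; max corrections "
            + str([round(w.max_correction, 4) for w in warps])
        )
    elif not config.align:
        log.append("alignment disabled")

    limits = config.element_limits()
    table = config.artifact_table()
    blanks = blanks or []
    solvent = [b for b in blanks if b.role == "solvent_blank"]
    procedural = [b for b in blanks if b.role == "procedural_blank"]
    if not solvent:
        log.append("warning: no solvent blank provided")
    if not procedural:
        log.append("warning: no procedural blank provided")

    def detect_and_group(run: Run) -> list[Feature]:
        feats = find_features(run, config)
        feats, iso_log = fold_isotopologues(feats, rt_tol=config.rt_tol)
        removal.extend(iso_log)
        comps = group_adducts(
            feats, table, mode=config.grouping_mode, limits=limits,
            tol_ppm=config.tol_ppm, detection_floor=config.min_intensity,
        )
        kept, art_log = remove_artifacts(comps)
        removal.extend(art_log)
        return kept

    blank_features = {
        "solvent_blank": [f for b in solvent for f in detect_and_group(b)],
        "procedural_blank": [f for b in procedural for f in detect_and_group(b)],
    }

    all_rows: list[dict] = []
    assignments: list[Assignment] = []
    feature_rows: list[dict] = []
    for run in samples:
        feats = find_features(run, config)
        counts[f"{run.sample}:detected"] = len(feats)
        for f in feats:
            feature_rows.append(
                {
                    "feature_id": f.feature_id, "sample": f.sample, "mz": f.mz,
                    "rt": f.rt, "area": f.area, "apex": f.apex_intensity,
                    "sn": f.sn, "n_scans": f.n_scans,
                }
            )
        feats, iso_log = fold_isotopologues(feats, rt_tol=config.rt_tol)
        removal.extend(iso_log)
        comps = group_adducts(
            feats, table, mode=config.grouping_mode, limits=limits,
            tol_ppm=config.tol_ppm, detection_floor=config.min_intensity,
        )
        counts[f"{run.sample}:components"] = len(comps)
        kept, art_log = remove_artifacts(comps)
        removal.extend(art_log)
        kept, blk_log = blank_subtract(
            kept,
            blank_features["solvent_blank"] or None,
            blank_features["procedural_blank"] or None,
            ratio_threshold=config.blank_ratio,
            mz_tol_ppm=config.mz_tol_ppm,
            rt_tol=config.rt_tol,
        )
        removal.extend(blk_log)
        counts[f"{run.sample}:after_blanks"] = len(kept)

        n_assigned = 0
        for f in kept:
            sp = ION_SPECIES[f.species_label or table.preferred[run.polarity]]
            a = assign_feature(
                f.feature_id,
                f.mz,
                sp,
                observed_isotopes=f.isotopes if f.isotopes.get("A") else None,
                limits=limits,
                tol_ppm=config.tol_ppm,
                isotope_tol=config.isotope_tol,
                rules=config.erroneous_rules(),
                detection_floor=config.min_intensity,
                ambiguity_ppm=config.ambiguity_ppm,
            )
            assignments.append(a)
            row: dict = {
                "feature_id": f.feature_id,
                "sample": f.sample,
                "mz": f.mz,
                "rt": f.rt,
                "area": f.area,
                "sn": f.sn,
                "adduct": sp.label,
                "formula": str(a.formula) if a.formula else "",
                "ppm_error": a.ppm_error,
                "status": a.status,
                "n_candidates": a.n_candidates,
                "isotope_dev_a1": a.isotope.dev_a1 if a.isotope else None,
                "isotope_dev_a2": a.isotope.dev_a2 if a.isotope else None,
            }
            if a.status in ("assigned", "ambiguous"):
                n_assigned += 1
                m = metrics(a.formula, modified_ai=config.modified_ai)
                row.update(
                    {
                        "mw_mono": m.mw_mono, "mw_nominal": m.mw_nominal,
                        "dbe": m.dbe, "dbe_c": m.dbe_c, "oc": m.oc, "hc": m.hc,
                        "nc": m.nc, "sc": m.sc, "osc": m.osc, "ai": m.ai,
                        "comp_class": m.comp_class,
                    }
                )
            else:
                removal.append(
                    {"feature_id": f.feature_id, "reason": f"formula_{a.status}"}
                )
            # MS2 identification
            row["compound"] = ""
            row["score"] = None
            row["level"] = 5
            if a.status in ("assigned", "ambiguous"):
                row["level"] = assign_confidence(
                    True, a.status == "assigned", has_ms2=False
                )
            queries = (ms2_spectra or {}).get(run.sample, [])
            q = _match_query(queries, f, config)
            if q is not None and a.status in ("assigned", "ambiguous"):
                row["level"] = assign_confidence(True, a.status == "assigned", True)
            if library and q is not None:
                hits = search(
                    q, library, min_score=config.min_score,
                    precursor_tol_ppm=config.precursor_tol_ppm,
                    frag_tol=config.frag_tol,
                )
                if hits:
                    best = hits[0]
                    row["compound"] = best.entry.name
                    row["score"] = best.score
                    row["level"] = assign_confidence(
                        a.formula is not None,
                        a.status == "assigned",
                        True,
                        match=best,
                        rt_check=best.rt_deviation is not None,
                        rt_window=config.rt_id_window,
                    )
            all_rows.append(row)
        counts[f"{run.sample}:assigned"] = n_assigned
        counts[f"{run.sample}:identified"] = sum(
            1 for r in all_rows if r["sample"] == run.sample and r["compound"]
        )
        log.append(
            f"{run.sample}: detected {counts[f'{run.sample}:detected']}, "
            f"components {counts[f'{run.sample}:components']}, "
            f"after blanks {counts[f'{run.sample}:after_blanks']}, "
            f"assigned {n_assigned}"
        )

    final = pd.DataFrame.from_records(all_rows)
    grouped = None
    sources = None
    if len(final):
        assigned_mask = final["status"].isin(["assigned", "ambiguous"]) & (
            final["formula"] != ""
        )
        gparts = []
        for sample_name, sub in final[assigned_mask].groupby("sample"):
            from .chem import parse_formula

            rows = [
                (parse_formula(f), a)
                for f, a in zip(sub["formula"], sub["area"])
            ]
            if rows:
                gparts.append(
                    group_composition(rows, sample=sample_name, carbon_bins=config.carbon_bins)
                )
        if gparts:
            grouped = pd.concat(gparts, ignore_index=True)
        if config.source_categories:
            sparts = []
            for sample_name, sub in final.groupby("sample"):
                ident = [
                    (c, a) for c, a in zip(sub["compound"], sub["area"]) if c
                ]
                if ident:
                    sparts.append(
                        source_report(
                            ident, config.source_categories,
                            total_area=float(sub["area"].sum()), sample=sample_name,
                        )
                    )
            if sparts:
                sources = pd.concat(sparts, ignore_index=True)

    return PipelineResult(
        features=pd.DataFrame.from_records(feature_rows),
        assignments=assignments,
        table=final,
        grouped=grouped,
        sources=sources,
        removal_log=pd.DataFrame.from_records(removal),
        stage_counts=counts,
        config=config,
        log_lines=log,
    )


def _match_query(
    queries: list[MS2Spectrum], f: Feature, config: PipelineConfig
) -> MS2Spectrum | None:
    tol = f.mz * config.precursor_tol_ppm * 1e-6
    best = None
    for q in queries:
        if abs(q.precursor_mz - f.mz) > tol:
            continue
        if q.rt is not None and abs(q.rt - f.rt) > max(config.rt_tol, 0.2):
            continue
        if best is None or abs(q.precursor_mz - f.mz) < abs(best.precursor_mz - f.mz):
            best = q
    return best
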