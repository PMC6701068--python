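"""End-to-end workflow: sequences -> pI -> profiles -> correlations -> regression.

Stage order mirrors the analysis the package implements: dataset filters,
pI computation, whole-proteome and per-compartment histograms, reference-point
localization profiles, share-vs-pI correlations, and the environment
regression of compartment mean pI on organelle pH and membrane charge.
All outputs are TSV with headers (pI to three decimals, statistics to four),
plus a JSON manifest that suffices to replay the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .environment import load_environment_table
from .errors import InsufficientDataError, PiscapeError
from .pi_engine import batch_pi, load_scheme
from .profiling import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_RANGE,
    DEFAULT_REFERENCE_POINTS,
    extract_extreme_subset,
    per_localization_histograms,
    reference_profile,
    share_curve_correlation,
)
from .regression import compartment_regression
from .sequence_io import (
    attach_localizations,
    filter_by_length,
    read_fasta,
    read_localization_table,
    redundancy_screen,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated knobs for one pipeline run; defaults match the standard analysis."""

    scheme: str = "bjellqvist"
    min_len: int = 50
    identity_threshold: float = 0.9
    skip_redundancy: bool = False
    bin_width: float = DEFAULT_BIN_WIDTH
    pi_range: tuple[float, float] = DEFAULT_RANGE
    reference_points: tuple[float, ...] = DEFAULT_REFERENCE_POINTS
    window: float = DEFAULT_BIN_WIDTH
    min_count: int = 20
    extreme_threshold: float = 11.5
    exclude: tuple[str, ...] = ("cytoskeleton",)
    regression_mode: str = "both"
    run_regression: bool = True
    seed: int = 0
    out_dir: str = "piscape_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(
    config: PipelineConfig,
    fasta: str | Path,
    localization_tsv: str | Path,
) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns a summary dict (also serialised as ``manifest.json``).  Any stage
    error aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = load_scheme(config.scheme)
    stage = "read"
    try:
        records = read_fasta(fasta)
        n_read = len(records)

        stage = "filter"
        records = filter_by_length(records, config.min_len)
        n_length = len(records)
        if not config.skip_redundancy:
            records = redundancy_screen(records, config.identity_threshold)
        n_unique = len(records)

        stage = "localization"
        loc_map = read_localization_table(localization_tsv)
        records, unlabelled = attach_localizations(records, loc_map)
        if unlabelled:
            logger.info("%d records without localization dropped", len(unlabelled))

        stage = "pi"
        records = batch_pi(records, scheme)
        _write_tsv(
            out / "protein_pi.tsv",
            ["id", "length", "pi", "localization"],
            [[r.id, len(r), f"{r.pi:.3f}", r.localization] for r in records],
        )

        stage = "histograms"
        hists = per_localization_histograms(records, config.bin_width, config.pi_range)
        hist_rows = []
        for label, h in sorted(hists.items()):
            for lo, hi, c in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
                hist_rows.append([label, f"{lo:.2f}", f"{hi:.2f}", int(c)])
        _write_tsv(out / "histograms.tsv", ["label", "bin_lo", "bin_hi", "count"], hist_rows)
        means = {
            label: h.mean_pi for label, h in hists.items() if label != "all"
        }
        _write_tsv(
            out / "compartment_means.tsv",
            ["label", "n", "mean_pi"],
            [[lab, hists[lab].n, f"{m:.3f}"] for lab, m in sorted(means.items())],
        )

        stage = "reference_profiles"
        profile_rows = []
        for ref in config.reference_points:
            prof = reference_profile(records, ref, config.window)
            for label, frac in prof.fractions.items():
                profile_rows.append([f"{ref:.2f}", label, prof.n, f"{frac:.4f}"])
        _write_tsv(
            out / "reference_profiles.tsv",
            ["ref_pi", "label", "n_window", "fraction"],
            profile_rows,
        )

        stage = "share_correlations"
        share_rows = []
        share_correlations = {}
        for label in sorted(means):
            try:
                res = share_curve_correlation(
                    records, label, config.bin_width, config.pi_range, config.min_count
                )
            except PiscapeError as exc:
                logger.info("share correlation skipped for %s: %s", label, exc)
                continue
            share_correlations[label] = res
            share_rows.append([label, f"{res.r:.4f}", res.n, f"{res.p:.4f}"])
        _write_tsv(
            out / "share_correlations.tsv", ["label", "pearson_r", "n_bins", "p"], share_rows
        )

        stage = "extreme_subset"
        extreme = extract_extreme_subset(records, config.extreme_threshold)
        _write_tsv(
            out / "extreme_subset.tsv",
            ["id", "pi", "localization"],
            [[r.id, f"{r.pi:.3f}", r.localization] for r in extreme],
        )

        stage = "regression"
        regression_rows = []
        if config.run_regression:
            try:
                fits = compartment_regression(
                    load_environment_table(),
                    means,
                    mode=config.regression_mode,  # type: ignore[arg-type]
                    exclude=set(config.exclude),
                )
            except InsufficientDataError as exc:
                logger.warning("regression skipped: %s", exc)
                fits = []
            for rank, fit in enumerate(fits[:25], start=1):
                sp = fit.spearman_fit
                regression_rows.append(
                    [
                        rank,
                        fit.family.name,
                        fit.family.kind,
                        f"{fit.r2:.4f}",
                        f"{sp.r:.4f}" if sp else "NA",
                        f"{sp.p:.4f}" if sp else "NA",
                        fit.n,
                        fit.format_equation(("pH", "charge")),
                    ]
                )
        _write_tsv(
            out / "regression_fits.tsv",
            ["rank", "family", "kind", "r2", "spearman_r", "spearman_p", "n", "equation"],
            regression_rows,
        )
    except PiscapeError as exc:
        raise type(exc)(f"pipeline stage {stage!r}: {exc}") from exc

    summary = {
        "config": config.to_dict(),
        "version": __version__,
        "inputs": {"fasta": str(fasta), "localization": str(localization_tsv)},
        "counts": {
            "read": n_read,
            "length_filtered": n_length,
            "non_redundant": n_unique,
            "labelled": len(records),
            "extreme": len(extreme),
        },
        "compartment_means": {k: round(v, 3) for k, v in sorted(means.items())},
        "share_correlations": {
            k: {"r": round(v.r, 4), "p": round(v.p, 4), "n": v.n}
            for k, v in sorted(share_correlations.items())
        },
        "top_regression": regression_rows[0][1] if regression_rows else None,
    }
    _write_tsv(
        out / "summary.tsv",
        ["stage", "count"],
        [[k, v] for k, v in summary["counts"].items()],
    )
    (out / "manifest.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
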