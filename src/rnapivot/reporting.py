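"""Tab-separated report writers with self-describing headers.

Every report starts with comment lines naming the tool version and the
configuration hash, and floats are printed with three decimals, so repeated
runs with identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

from . import __version__
from .cascade_analysis import CascadeRow, ContactEdge
from .pivot_detection import DeviationProfile, MobileRegion, PivotCall
from .superposition import SuperpositionResult

__all__ = [
    "write_pivot_report",
    "write_cascade_report",
    "write_network_edges",
    "write_superposition_report",
    "write_profile",
    "write_mobile_regions",
]


def _fmt(x: float | int | None) -> str:
    if x is None:
        return "NA"
    if isinstance(x, int):
        return str(x)
    if x != x:  # NaN
        return "NA"
    return f"{x:.3f}"


def _header(fh, columns: list[str], config_hash: str) -> None:
    fh.write(f"# rnapivot {__version__}\tconfig_hash={config_hash}\n")
    fh.write("\t".join(columns) + "\n")


def write_pivot_report(calls: list[PivotCall], path: str | Path,
                       config_hash: str = "") -> None:
    with open(path, "w") as fh:
        _header(fh, ["helix_id", "chain", "pivot_location", "motif_class",
                     "tip_residue", "displacement_A", "stem_residual_A",
                     "flags"], config_hash)
        for c in calls:
            fh.write("\t".join([
                c.helix_id, c.chain, _fmt(c.pivot_location), c.motif_class,
                _fmt(c.tip_residue), _fmt(c.displacement),
                _fmt(c.stem_residual), ",".join(c.flags) or "-",
            ]) + "\n")


def write_cascade_report(rows: list[CascadeRow], path: str | Path,
                         config_hash: str = "") -> None:
    with open(path, "w") as fh:
        _header(fh, ["downstream_helix", "upstream_helix",
                     "displacement_upstream_aligned_A",
                     "displacement_individual_A", "amplification", "flags"],
                config_hash)
        for r in rows:
            fh.write("\t".join([
                r.downstream_helix_id, r.upstream_helix_id,
                _fmt(r.displacement_upstream_aligned),
                _fmt(r.displacement_individual), _fmt(r.amplification),
                ",".join(r.flags) or "-",
            ]) + "\n")


def write_network_edges(edges: list[ContactEdge], path: str | Path,
                        config_hash: str = "") -> None:
    with open(path, "w") as fh:
        _header(fh, ["a", "b", "kind", "value"], config_hash)
        for e in edges:
            fh.write(f"{e.pivot_a}\t{e.pivot_b}\t{e.kind}\t{_fmt(e.value)}\n")


def write_superposition_report(results: dict[str, SuperpositionResult],
                               path: str | Path, config_hash: str = "") -> None:
    with open(path, "w") as fh:
        _header(fh, ["comparison", "n_input", "n_rejected", "rmsd_all_A",
                     "rmsd_kept_A", "cycles"], config_hash)
        for name, sr in results.items():
            fh.write(f"{name}\t{sr.n_input}\t{sr.n_rejected}\t"
                     f"{_fmt(sr.rmsd_all)}\t{_fmt(sr.rmsd_kept)}\t{sr.cycles_run}\n")


def write_profile(profile: DeviationProfile, path: str | Path,
                  config_hash: str = "") -> None:
    with open(path, "w") as fh:
        _header(fh, ["residue", "deviation_A"], config_hash)
        fh.write(f"# helix={profile.helix_id}\tchain={profile.chain}\t"
                 f"metric={profile.metric}\n")
        for num, d in profile.entries:
            fh.write(f"{num}\t{_fmt(d)}\n")


def write_mobile_regions(regions: list[MobileRegion], path: str | Path,
                         config_hash: str = "") -> None:
    with open(path, "w") as fh:
        _header(fh, ["chain", "start", "end", "length", "peak_deviation_A",
                     "mean_deviation_A"], config_hash)
        for r in regions:
            fh.write(f"{r.chain}\t{r.start}\t{r.end}\t{len(r)}\t"
                     f"{_fmt(r.peak_deviation)}\t{_fmt(r.mean_deviation)}\n")
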