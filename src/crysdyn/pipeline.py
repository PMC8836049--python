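"""End-to-end analysis orchestration and tabular report assembly.

`run_pipeline` executes, in order: RMSD/RMSF → essential-dynamics
projections → contact-fraction series (whole protein, domains, configured
regions) → ensemble contact map → secondary-structure matrix and unfolding
events → aromatic persistence and cluster events → interdomain motion
fractions (when two domain regions are configured).  Every table is plain
TSV with a one-line ``#`` parameter header; the manifest records a sha256
checksum per table so reruns can be byte-compared.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aromatics import (
    aromatic_residues,
    cluster_formation_events,
    persistence_percentage,
)
from .contacts import (
    contact_fraction_series,
    ensemble_contact_map,
    region_pair_contact_summary,
    subtractive_map,
)
from .io_model import RegionMap, Trajectory, load_regions, read_trajectory, select_atoms
from .kinematics import motion_fraction, pca_essential, project_frames, rmsd_series, rmsf_per_residue
from .secondary_structure import detect_unfolding_events, ss_timeseries

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "compare_runs"]


@dataclass
class PipelineConfig:
    traj_path: str
    out_dir: str
    regions_path: str | None = None
    use_default_regions: bool = True
    dt_ns: float = 0.25
    stride: int = 1
    cutoff: float = 6.5
    band: tuple[float, float] = (4.5, 7.0)
    event_threshold: float = 50.0
    event_persistence: int = 5
    fixed_domain: str | None = None
    moving_domain: str | None = None
    seed: int = 0


@dataclass
class ReportBundle:
    out_dir: str
    manifest: dict[str, dict] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def register(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.manifest[name] = {"path": str(path), "sha256": digest}

    def write(self) -> Path:
        out = Path(self.out_dir) / "manifest.json"
        out.write_text(
            json.dumps({"manifest": self.manifest, "metadata": self.metadata}, indent=2)
        )
        return out

    def verify(self) -> dict[str, bool]:
        ok = {}
        for name, entry in self.manifest.items():
            p = Path(entry["path"])
            ok[name] = (
                p.exists()
                and hashlib.sha256(p.read_bytes()).hexdigest() == entry["sha256"]
            )
        return ok


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_run_regions(run_dir: Path) -> RegionMap | None:
    cfg = run_dir / "regions.cfg"
    if cfg.exists():
        return load_regions(cfg, include_defaults=False)
    return None


def run_pipeline(
    config: PipelineConfig,
    traj: Trajectory | None = None,
    regions: RegionMap | None = None,
    log=print,
) -> ReportBundle:
    """Run every analysis stage and assemble the TSV report bundle.

    ``traj``/``regions`` may be passed directly (library use); otherwise they
    are loaded from the configured paths.  Identical config + inputs produce
    identical table checksums.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if traj is None:
        traj = read_trajectory(config.traj_path, dt_ns=config.dt_ns)
    if regions is None:
        regions = load_regions(config.regions_path, include_defaults=config.use_default_regions)
    bundle = ReportBundle(out_dir=str(out))
    params = asdict(config)
    # header omits output paths so reruns into other directories byte-match
    header = " ".join(
        f"{k}={v}" for k, v in params.items() if k not in ("out_dir", "traj_path")
    )
    stage_t = time.time()

    def _stage(name):
        nonlocal stage_t
        log(f"[crysdyn] stage={name} elapsed={time.time() - stage_t:.2f}s")
        stage_t = time.time()

    try:
        mainchain = select_atoms(traj.topology, "mainchain")
        rmsd = rmsd_series(traj, selection=mainchain)
        _write_tsv(
            pd.DataFrame({"time_ns": rmsd.times_ns, "rmsd_A": rmsd.values}),
            out / "rmsd.tsv",
            header,
        )
        bundle.register("rmsd", out / "rmsd.tsv")
        residues, rmsf = rmsf_per_residue(traj, mainchain)
        _write_tsv(
            pd.DataFrame({"residue": residues, "rmsf_A": rmsf}),
            out / "rmsf.tsv",
            header,
        )
        bundle.register("rmsf", out / "rmsf.tsv")
        _stage("rmsd_rmsf")

        model = pca_essential(traj, mainchain)
        proj = project_frames(traj, model, k=2)
        _write_tsv(
            pd.DataFrame(
                {"time_ns": traj.times_ns, "pc1": proj[:, 0], "pc2": proj[:, 1]}
            ),
            out / "pca_projections.tsv",
            header,
        )
        bundle.register("pca_projections", out / "pca_projections.tsv")
        _stage("pca")

        scopes: list[tuple[str, object]] = [("whole", None)]
        scopes += [(name, name) for name in regions]
        rows = []
        for scope, region in scopes:
            try:
                qs = contact_fraction_series(
                    traj,
                    stride=config.stride,
                    region=region,
                    cutoff=config.cutoff,
                    regions=regions,
                )
            except ValueError:
                continue  # region with no reference contacts
            for t, v in zip(qs.series.times_ns, qs.series.values):
                rows.append({"time_ns": t, "Q": v, "scope": scope})
        _write_tsv(pd.DataFrame(rows), out / "q_series.tsv", header)
        bundle.register("q_series", out / "q_series.tsv")

        cmap = ensemble_contact_map(traj, stride=config.stride, cutoff=config.cutoff)
        np.savetxt(
            out / "contact_map.tsv",
            cmap.frequencies,
            delimiter="\t",
            fmt="%.6g",
            header=header,
        )
        np.savetxt(
            out / "contact_ref.tsv",
            cmap.reference_indicator,
            delimiter="\t",
            fmt="%.6g",
            header=header,
        )
        bundle.register("contact_map", out / "contact_map.tsv")
        bundle.register("contact_ref", out / "contact_ref.tsv")
        _stage("contacts")

        ssm = ss_timeseries(traj, stride=config.stride)
        with open(out / "ss_matrix.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            fh.write("residue\t" + "\t".join(f"{t:g}" for t in ssm.times_ns) + "\n")
            for r in range(ssm.n_residues):
                fh.write(
                    f"{ssm.author_numbers[r]}\t" + "\t".join(ssm.labels[r]) + "\n"
                )
        bundle.register("ss_matrix", out / "ss_matrix.tsv")
        events = detect_unfolding_events(
            ssm,
            regions,
            threshold=config.event_threshold,
            persistence=config.event_persistence,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "region": e.region,
                        "onset_ns": e.onset_ns,
                        "kind": e.kind,
                        "beta_before_pct": e.beta_before_pct,
                        "beta_after_pct": e.beta_after_pct,
                    }
                    for e in events
                ],
                columns=["region", "onset_ns", "kind", "beta_before_pct", "beta_after_pct"],
            ),
            out / "events.tsv",
            header,
        )
        bundle.register("events", out / "events.tsv")
        _stage("secondary_structure")

        rings = sorted(aromatic_residues(traj.topology))
        rows = []
        for a, b in combinations(rings, 2):
            rows.append(
                {
                    "res_a": a,
                    "res_b": b,
                    "persistence_pct": persistence_percentage(
                        traj, a, b, stride=config.stride, band=config.band
                    ),
                }
            )
        _write_tsv(
            pd.DataFrame(rows, columns=["res_a", "res_b", "persistence_pct"]),
            out / "persistence.tsv",
            header,
        )
        bundle.register("persistence", out / "persistence.tsv")
        clusters = cluster_formation_events(traj, stride=config.stride, band=config.band)
        _write_tsv(
            pd.DataFrame(
                [
                    {"onset_ns": c.onset_ns, "members": "+".join(map(str, sorted(c.members)))}
                    for c in clusters
                ],
                columns=["onset_ns", "members"],
            ),
            out / "clusters.tsv",
            header,
        )
        bundle.register("clusters", out / "clusters.tsv")
        _stage("aromatics")

        if config.fixed_domain and config.moving_domain:
            mf = motion_fraction(
                traj,
                config.fixed_domain,
                config.moving_domain,
                stride=config.stride,
                regions=regions,
            )
            _write_tsv(
                pd.DataFrame(
                    mf["per_frame"],
                    columns=["time_ns", "angle_deg", "pct_closure", "label"],
                ),
                out / "motion.tsv",
                header + f" fraction_closure={mf['fraction_closure']:.4g}"
                f" fraction_twist={mf['fraction_twist']:.4g}",
            )
            bundle.register("motion", out / "motion.tsv")
            bundle.metadata["motion_fractions"] = {
                "fraction_closure": mf["fraction_closure"],
                "fraction_twist": mf["fraction_twist"],
                "n_excluded": mf["n_excluded"],
            }
            _stage("motion")
    except Exception as exc:
        bundle.metadata["aborted_stage"] = repr(exc)
        bundle.write()
        raise RuntimeError(f"pipeline aborted: {exc}") from exc

    bundle.metadata.update(
        parameters=params,
        version=__version__,
        seed=config.seed,
        wall_time_s=round(time.time() - t_start, 3),
        n_frames=traj.n_frames,
        n_residues=traj.topology.n_residues,
    )
    bundle.write()
    log(f"[crysdyn] done in {bundle.metadata['wall_time_s']}s -> {out}")
    return bundle


def compare_runs(run_a: str | Path, run_b: str | Path, out_dir: str | Path, mode: str = "raw"):
    """Subtractive contact map between two completed runs.

    Loads each run's ensemble map and frame-0 indicator, writes the signed
    A − B map for the requested mode plus per-region-pair block means for
    every pair of regions defined in run A's region config (when present).
    Negative entries mark contact frequency lower in run A.
    """
    from .contacts import ContactMap

    run_a, run_b, out = Path(run_a), Path(run_b), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def load(run):
        freq = np.loadtxt(run / "contact_map.tsv", delimiter="\t")
        ref = np.loadtxt(run / "contact_ref.tsv", delimiter="\t")
        authors = np.arange(1, freq.shape[0] + 1)
        return ContactMap(freq, 0, ref, authors)

    a, b = load(run_a), load(run_b)
    diff = subtractive_map(a, b, mode=mode)
    np.savetxt(out / f"subtractive_{mode}.tsv", diff, delimiter="\t", fmt="%.6g")
    rows = []
    regions = _load_run_regions(run_a)
    if regions:
        for ra, rb in combinations(sorted(regions), 2):
            try:
                rows.append(
                    {
                        "region_a": ra,
                        "region_b": rb,
                        "mean_diff": region_pair_contact_summary(
                            a, ra, rb, regions=regions, matrix=diff
                        ),
                    }
                )
            except ValueError:
                continue
    pd.DataFrame(rows, columns=["region_a", "region_b", "mean_diff"]).to_csv(
        out / "region_pair_summary.tsv", sep="\t", index=False
    )
    return diff
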