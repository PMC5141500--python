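"""Activation-state fingerprint of a receptor structure or ensemble.

One call computes the full battery of geometric activation indicators
for a class A GPCR, addressed through Ballesteros-Weinstein labels:

* connector packing: minimum side-chain heavy-atom distances between
  positions 5.50-3.40, 3.40-6.44 and 5.50-6.44, as population
  histograms;
* microswitch rotamers: chi2 of 6.48 and chi1 of 6.44 distributions;
* G-protein interface: 2-D density of the TM3-TM6 (3.50-6.30) vs
  TM3-TM7 (3.50-7.53) CA distances;
* the 5.58-7.53 distance (the tyrosine-lock contact of the NPxxY
  region), summarised per frame;
* counts of persistent interhelical hydrogen-bond / van-der-Waals
  contacts split by the membrane half of the participating residues.

Reports are deterministic: identical input and config produce
byte-identical report directories.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .contacts import ContactCriteria, ContactSeries, contacts_to_tsv, interhelical_persistence
from .distributions import Density2D, Histogram1D, density2d, histogram
from .errors import ConfigurationError, EmptySeriesError, IncomparableReportsError
from .geometry import DistanceSeries, chi_series, distance_series
from .structures import BWMap, Ensemble, Structure

REQUIRED_LABELS = ("3.40", "3.50", "5.50", "5.58", "6.30", "6.44", "6.48", "7.53")

CONNECTOR_PAIRS = (("5.50", "3.40"), ("3.40", "6.44"), ("5.50", "6.44"))

HALF_BUCKETS = ("intracellular", "extracellular", "spanning")


@dataclass(frozen=True)
class FingerprintBins:
    distance: float = 0.25  # Angstrom
    angle: float = 5.0  # degrees
    grid: float = 0.5  # Angstrom, 2-D interface map

    def as_dict(self) -> dict:
        return {"distance": self.distance, "angle": self.angle, "grid": self.grid}


@dataclass
class FingerprintReport:
    connector: dict[tuple[str, str], Histogram1D]
    rotamers: dict[str, Histogram1D]  # "chi2_6.48", "chi1_6.44"
    interface: Density2D
    npxxy_contact: dict[str, float]  # summary stats of the 5.58-7.53 distance
    contacts: dict[str, dict[str, int]]  # kind -> half bucket -> count
    contact_series: list[ContactSeries]
    provenance: dict
    n_frames: int = 1

    @property
    def config_hash(self) -> str:
        return self.provenance["config_hash"]


def _config_dict(criteria: ContactCriteria, bins: FingerprintBins) -> dict:
    return {"criteria": criteria.as_dict(), "bins": bins.as_dict()}


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _hash_input(ensemble: Ensemble) -> str:
    h = hashlib.sha256()
    sig = [
        (r.chain_id, r.seq_number, a.name)
        for r, a, _ in ensemble.topology.iter_atoms()
    ]
    h.update(repr(sig).encode())
    h.update(np.ascontiguousarray(np.round(ensemble.frames, 6)).tobytes())
    return h.hexdigest()[:16]


def fingerprint(
    source: Structure | Ensemble,
    bwmap: BWMap,
    criteria: ContactCriteria | None = None,
    bins: FingerprintBins | None = None,
) -> FingerprintReport:
    """Compute the fingerprint of one structure or conformational ensemble.

    A single :class:`Structure` yields degenerate single-bin histograms
    (point values); an :class:`Ensemble` yields the full distributions.
    Missing BW labels raise :class:`ConfigurationError` naming them.
    """
    criteria = criteria or ContactCriteria()
    bins = bins or FingerprintBins()
    missing = [lbl for lbl in REQUIRED_LABELS if lbl not in bwmap._by_label]
    if missing:
        raise ConfigurationError(f"BW map lacks required labels: {missing}")
    if isinstance(source, Structure):
        ensemble = Ensemble.from_structure(source)
    else:
        ensemble = source
    if ensemble.n_frames == 0:
        raise EmptySeriesError("empty ensemble")

    seq = {lbl: bwmap.seq_of(lbl) for lbl in REQUIRED_LABELS}

    connector = {}
    for la, lb in CONNECTOR_PAIRS:
        series = distance_series(ensemble, seq[la], seq[lb], "min_sidechain_heavy")
        connector[(la, lb)] = histogram(series, bins.distance)

    rotamers = {
        "chi2_6.48": histogram(chi_series(ensemble, seq["6.48"], 2), bins.angle, angular=True),
        "chi1_6.44": histogram(chi_series(ensemble, seq["6.44"], 1), bins.angle, angular=True),
    }

    tm36 = distance_series(ensemble, seq["3.50"], seq["6.30"], "ca_ca")
    tm37 = distance_series(ensemble, seq["3.50"], seq["7.53"], "ca_ca")
    interface = density2d(tm36, tm37, bins.grid)

    npxxy = distance_series(ensemble, seq["5.58"], seq["7.53"], "ca_ca")
    vals = npxxy.values[np.isfinite(npxxy.values)]
    npxxy_summary = {
        "mean": float(vals.mean()) if vals.size else float("nan"),
        "std": float(vals.std()) if vals.size else float("nan"),
        "min": float(vals.min()) if vals.size else float("nan"),
        "max": float(vals.max()) if vals.size else float("nan"),
        "n_missing": int(np.sum(~np.isfinite(npxxy.values))),
    }

    series = interhelical_persistence(ensemble, bwmap, criteria)
    counts = {
        kind: {bucket: 0 for bucket in HALF_BUCKETS} for kind in ("hbond", "vdw")
    }
    for s in series:
        counts[s.kind][s.half_bucket] += 1

    cfg = _config_dict(criteria, bins)
    provenance = {
        "tool": "gpcrfp",
        "version": __version__,
        "config": cfg,
        "config_hash": _hash_config(cfg),
        "input_hash": _hash_input(ensemble),
        "input_label": ensemble.topology.label,
        "n_frames": ensemble.n_frames,
    }
    return FingerprintReport(
        connector=connector,
        rotamers=rotamers,
        interface=interface,
        npxxy_contact=npxxy_summary,
        contacts=counts,
        contact_series=series,
        provenance=provenance,
        n_frames=ensemble.n_frames,
    )


# ---------------------------------------------------------------------------
# report directory
# ---------------------------------------------------------------------------

def write_report(report: FingerprintReport, outdir: str | Path, bwmap: BWMap) -> Path:
    """Write the report as a directory of TSVs plus provenance.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flat = []
    for (la, lb), h in report.connector.items():
        flat.append((f"connector_peak_{la}_{lb}_A", f"{h.peak_location:.6f}"))
        h.to_tsv(outdir / f"connector_{la}_{lb}.tsv")
    for key, h in report.rotamers.items():
        flat.append((f"rotamer_peak_{key}_deg", f"{h.peak_location:.6f}"))
        h.to_tsv(outdir / f"rotamer_{key}.tsv")
    mx, my = report.interface.modal_center
    flat.append(("interface_modal_tm3_tm6_A", f"{mx:.6f}"))
    flat.append(("interface_modal_tm3_tm7_A", f"{my:.6f}"))
    report.interface.to_tsv(outdir / "interface_density.tsv")
    for k, v in report.npxxy_contact.items():
        flat.append((f"npxxy_5.58_7.53_{k}", f"{v:.6f}" if isinstance(v, float) else str(v)))
    for kind in ("hbond", "vdw"):
        for bucket in HALF_BUCKETS:
            flat.append(
                (f"contacts_{kind}_{bucket}", str(report.contacts[kind][bucket]))
            )
    criteria = ContactCriteria(**report.provenance["config"]["criteria"])
    contacts_to_tsv(report.contact_series, bwmap, outdir / "contacts.tsv", criteria)
    lines = ["key\tvalue"] + [f"{k}\t{v}" for k, v in flat]
    (outdir / "fingerprint.tsv").write_text("\n".join(lines) + "\n")
    prov = json.dumps(report.provenance, sort_keys=True, indent=1)
    (outdir / "provenance.txt").write_text(prov + "\n")
    return outdir


# ---------------------------------------------------------------------------
# report comparison
# ---------------------------------------------------------------------------

@dataclass
class ReportDiff:
    connector_peak_shifts: dict[tuple[str, str], float]  # Angstrom (b - a)
    rotamer_peak_shifts: dict[str, float]  # degrees, wrapped
    contact_count_deltas: dict[str, dict[str, int]]  # kind -> bucket -> b - a
    interface_modal_shift: tuple[float, float]  # Angstrom along each axis
    npxxy_mean_delta: float

    def to_tsv(self, path) -> None:
        lines = ["metric\tdelta"]
        for (la, lb), d in self.connector_peak_shifts.items():
            lines.append(f"connector_{la}_{lb}\t{d:.6f}")
        for k, d in self.rotamer_peak_shifts.items():
            lines.append(f"rotamer_{k}\t{d:.6f}")
        for kind, buckets in self.contact_count_deltas.items():
            for b, d in buckets.items():
                lines.append(f"contacts_{kind}_{b}\t{d}")
        lines.append(f"interface_modal_tm3_tm6\t{self.interface_modal_shift[0]:.6f}")
        lines.append(f"interface_modal_tm3_tm7\t{self.interface_modal_shift[1]:.6f}")
        lines.append(f"npxxy_mean\t{self.npxxy_mean_delta:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def compare_reports(a: FingerprintReport, b: FingerprintReport) -> ReportDiff:
    """Structured per-metric difference (b minus a) of two reports.

    Reports must have been produced under the same configuration.
    """
    if a.config_hash != b.config_hash:
        raise IncomparableReportsError(
            f"config hashes differ: {a.config_hash} vs {b.config_hash}"
        )
    conn = {
        pair: b.connector[pair].peak_location - a.connector[pair].peak_location
        for pair in a.connector
    }
    def _wrap(d):
        return ((d + 180.0) % 360.0) - 180.0
    rot = {
        k: _wrap(b.rotamers[k].peak_location - a.rotamers[k].peak_location)
        for k in a.rotamers
    }
    cc = {
        kind: {
            bucket: b.contacts[kind][bucket] - a.contacts[kind][bucket]
            for bucket in a.contacts[kind]
        }
        for kind in a.contacts
    }
    ax, ay = a.interface.modal_center
    bx, by = b.interface.modal_center
    return ReportDiff(
        connector_peak_shifts=conn,
        rotamer_peak_shifts=rot,
        contact_count_deltas=cc,
        interface_modal_shift=(bx - ax, by - ay),
        npxxy_mean_delta=b.npxxy_contact["mean"] - a.npxxy_contact["mean"],
    )
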