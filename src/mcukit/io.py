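"""File formats: FASTA, newick, TSV/CSV tables, JSON sidecars, manifests.

All writers prepend a `#` header comment with the tool version and a
config hash so any output is traceable to the run that produced it; all
readers skip such comments, so every file round-trips through this module.
Coordinates are 0-based half-open internally and only converted to 1-based
in explicitly human-readable report columns.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .aequorin import CalibrationConstants, LuminescenceTrace
from .screen import Alignment, DomainHit, FamilyAssignment, ProfileModel


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg_hash: str = "") -> str:
    return f"# mcukit v{__version__} config={cfg_hash}\n"


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="")
               for sid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path) -> Alignment:
    pairs = list(read_fasta(path).items())
    return Alignment.from_pairs(pairs)


def write_alignment(path, aln: Alignment) -> None:
    write_fasta(path, dict(zip(aln.ids, aln.rows)))


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def write_tree(path, tree: dendropy.Tree) -> None:
    Path(path).write_text(tree.as_string(schema="newick",
                                         suppress_rooting=True))


def write_table(path, df: pd.DataFrame, cfg_hash: str = "",
                index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_hits(path, hits: list[DomainHit], cfg_hash: str = "") -> None:
    df = pd.DataFrame(
        [(h.seq_id, h.start, h.end, h.score, h.profile_id, h.iteration)
         for h in hits],
        columns=["seq_id", "start", "end", "score_bits", "profile_id",
                 "iteration"])
    write_table(path, df, cfg_hash)


def read_hits(path) -> list[DomainHit]:
    df = read_table(path)
    return [DomainHit(r.seq_id, int(r.start), int(r.end), float(r.score_bits),
                      r.profile_id,
                      None if pd.isna(r.iteration) else int(r.iteration))
            for r in df.itertuples()]


def write_assignments(path, assignments: dict[str, FamilyAssignment],
                      cfg_hash: str = "") -> None:
    df = pd.DataFrame(
        [(a.seq_id, a.family, ";".join(a.rule_trace))
         for a in assignments.values()],
        columns=["seq_id", "family", "rule_trace"])
    write_table(path, df.sort_values("seq_id"), cfg_hash)


def write_profile(path, profile: ProfileModel) -> None:
    payload = {
        "profile_id": profile.profile_id,
        "family_role": profile.family_role,
        "pseudocount_weight": profile.pseudocount_weight,
        "accept_threshold": profile.accept_threshold,
        "background": profile.background.tolist(),
        "log_odds": profile.log_odds.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_profile(path) -> ProfileModel:
    payload = json.loads(Path(path).read_text())
    return ProfileModel(np.array(payload["log_odds"]),
                        np.array(payload["background"]),
                        payload["pseudocount_weight"],
                        payload["accept_threshold"],
                        payload["profile_id"],
                        payload.get("family_role"))


def write_trace(path, trace: LuminescenceTrace) -> None:
    df = pd.DataFrame({"time_s": trace.times, "counts": trace.counts})
    df.to_csv(path, index=False)
    sidecar = {"dt": trace.dt, "lysis_counts": trace.lysis_counts,
               **{k: v for k, v in trace.meta.items()}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path) -> LuminescenceTrace:
    df = pd.read_csv(path, comment="#")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    meta = {k: v for k, v in sidecar.items() if k not in ("lysis_counts",)}
    return LuminescenceTrace(df["time_s"].to_numpy(), df["counts"].to_numpy(),
                             float(sidecar["lysis_counts"]), meta)


def read_plate(csv_path, meta_path
               ) -> tuple[dict[str, LuminescenceTrace], dict[str, str], dict]:
    """Plate CSV (well, time_s, counts) + metadata JSON.

    The metadata must provide ``lysis_counts`` and a group label per well;
    optional keys: ``stimulus_time``, ``constants`` (calibration overrides),
    ``smoothing_p``.
    """
    df = pd.read_csv(csv_path, comment="#")
    required = {"well", "time_s", "counts"}
    if not required <= set(df.columns):
        raise ValueError(f"plate CSV must have columns {sorted(required)}")
    meta = json.loads(Path(meta_path).read_text())
    plate: dict[str, LuminescenceTrace] = {}
    groups: dict[str, str] = {}
    for well, sub in df.groupby("well", sort=True):
        well = str(well)
        well_meta = meta.get("wells", {}).get(well)
        if well_meta is None or "lysis_counts" not in well_meta:
            raise ValueError(f"missing lysis_counts for well {well!r}")
        sub = sub.sort_values("time_s")
        plate[well] = LuminescenceTrace(sub["time_s"].to_numpy(),
                                        sub["counts"].to_numpy(),
                                        float(well_meta["lysis_counts"]))
        groups[well] = str(well_meta.get("group", "default"))
    return plate, groups, meta


def constants_from_meta(meta: dict) -> CalibrationConstants:
    over = meta.get("constants", {})
    return CalibrationConstants(
        lam=float(over.get("lambda", over.get("lam", 1.0))),
        k_r=float(over.get("K_R", 7.23e6)),
        k_tr=float(over.get("K_TR", 120.0)),
        n=float(over.get("n", 2.99)))


@dataclass
class RunManifest:
    config_hash: str
    tool_version: str = __version__
    started: float = field(default_factory=time.time)
    checksums: dict[str, str] = field(default_factory=dict)

    def record(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.checksums[path.name] = digest

    def write(self, path) -> None:
        payload = {"config_hash": self.config_hash,
                   "tool_version": self.tool_version,
                   "checksums": dict(sorted(self.checksums.items()))}
        Path(path).write_text(json.dumps(payload, indent=1))
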