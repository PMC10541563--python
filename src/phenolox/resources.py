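"""Packaged data resources: synthetic domain templates and anchor profiles.

The templates and references are synthetic consensus stand-ins (fixed
random 60–120-residue strings with the diagnostic residues planted at
known offsets), generated once and frozen as text resources. They are
mutually dissimilar enough that the detector's default thresholds
separate them cleanly. Users with curated references supply their own
FASTA + profile files through the same interfaces.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ilr
from typing import Dict

from Bio import SeqIO

from .residues import AnchorProfile, read_profile
from .seqio import SequenceRecord

#: role -> 0-based offset inside the TYROSINASE template
TYROSINASE_ROLE_OFFSETS = {
    "HisA1": 19,
    "HisA2": 23,
    "HisA3": 44,
    "gatekeeper": 49,
    "HisB1": 79,
    "HB1plus1": 80,
    "HisB2": 83,
    "HB2plus1": 84,
    "HisB3": 94,
    "waterkeeper": 99,
}

#: 0-based offset of the KFDV tetrapeptide inside the PPO1_KFDV template
KFDV_MOTIF_OFFSET = 39


def _data_path(name: str):
    return _ilr.files("phenolox.data").joinpath(name)


@lru_cache(maxsize=None)
def load_templates() -> Dict[str, str]:
    """The six per-domain synthetic consensus templates, keyed by domain."""
    with _ilr.as_file(_data_path("synthetic_templates.fasta")) as path:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def template_role_offsets() -> Dict[str, int]:
    return dict(TYROSINASE_ROLE_OFFSETS)


def _load_reference(fasta_name: str, family: str) -> SequenceRecord:
    with _ilr.as_file(_data_path(fasta_name)) as path:
        rec = next(SeqIO.parse(str(path), "fasta"))
    return SequenceRecord(
        id=rec.id, species="synthetic", kind="protein", seq=str(rec.seq)
    )


@lru_cache(maxsize=None)
def load_co_profile() -> AnchorProfile:
    """Catechol-oxidase anchor: concatenated tyrosinase + DWL + KFDV
    template domains with the ten diagnostic roles."""
    ref = _load_reference("synthetic_co_reference.fasta", "CO")
    with _ilr.as_file(_data_path("synthetic_co_profile.tsv")) as path:
        return read_profile(path, ref, "CO")


@lru_cache(maxsize=None)
def load_lacaao_profile() -> AnchorProfile:
    """Laccase/ascorbate-oxidase anchor: three concatenated Cu-oxidase
    template domains with H-A/H-B/H-C region histidines and NNX anchor."""
    ref = _load_reference("synthetic_lacaao_reference.fasta", "LAC_AAO")
    with _ilr.as_file(_data_path("synthetic_lacaao_profile.tsv")) as path:
        return read_profile(path, ref, "LAC_AAO")


def fixture_dir():
    """Path-like handle on the packaged end-to-end demo fixture."""
    return _ilr.files("phenolox.data").joinpath("fixture")
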