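"""Packaged fixtures: built-in ITS haplotypes and CAPS marker definitions.

The three built-in haplotypes A, B and C carry the published states at the 13
polymorphic columns of the 662-column clone alignment.  Full sequences are
not published, so the haplotypes are completed with a *synthetic* reference
background: a fixed-seed random sequence shared by all three types, with
gaps at columns 39 (B, C) and 475 (C) and flanking G's around column 334 so
that the superposed-chromatogram masking of the B-specific G is reproduced.
Everything that depends only on the 13 columns (typing, specific sites,
phenotype classes) is exact; the background is an arbitrary but deterministic
stand-in.

Marker fixtures are cut maps (amplicon length + per-allele cut coordinates)
calibrated so every published genotype->fragment row is reproduced exactly;
``build_synthetic_amplicon`` turns a cut map into a concrete sequence whose
scan-and-digest results match it, for end-to-end sequence-level checks.
"""

from __future__ import annotations

import json
import random
from functools import lru_cache
from importlib import resources

from .caps import ENZYMES, CAPSMarker, EnzymeSpec, GelModel, MarkerAllele
from .haplotypes import GAP, ITSHaplotype, RegionMap

_REFERENCE_SEED = 20160526  # fixed; the background is arbitrary but frozen

ITS_TYPES = ("A", "B", "C")


def _read_packaged(name: str) -> dict:
    with resources.files("itsloci.data").joinpath(name).open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def haplotype_config(path: str | None = None) -> dict:
    """The haplotype definition config (packaged Table-of-states by default)."""
    if path is None:
        return _read_packaged("haplotypes.json")
    with open(path) as fh:
        return json.load(fh)


def table3_columns() -> list[int]:
    return list(haplotype_config()["columns"])


def builtin_regions() -> RegionMap:
    cfg = haplotype_config()["regions"]
    return RegionMap(tuple((name, lo, hi) for name, (lo, hi) in cfg.items()))


@lru_cache(maxsize=None)
def build_reference_alignment() -> dict[str, str]:
    """Synthetic 662-column aligned sequences for the built-in haplotypes."""
    cfg = haplotype_config()
    n = cfg["alignment_length"]
    rng = random.Random(_REFERENCE_SEED)
    background = [rng.choice("ACGT") for _ in range(n)]
    # flanking G's around column 334: with the 1-bp deletion at column 39
    # shifting types B and C, the B-specific G at 334 adds no new peak
    background[332] = "G"
    background[334] = "G"
    # pin T's around column 269 so the C-specific A there stays detectable
    # in the superposed trace despite the 1-bp frame shift of types B and C
    background[267] = "T"
    background[269] = "T"
    out = {}
    for name, states in cfg["haplotypes"].items():
        seq = list(background)
        for col, s in states.items():
            seq[int(col) - 1] = s
        out[name] = "".join(seq)
    return out


@lru_cache(maxsize=None)
def builtin_haplotypes() -> tuple[ITSHaplotype, ...]:
    """The built-in A/B/C haplotypes with full (synthetic-background) sequences."""
    cfg = haplotype_config()
    seqs = build_reference_alignment()
    return tuple(
        ITSHaplotype(name, {int(c): s for c, s in states.items()}, seqs[name])
        for name, states in cfg["haplotypes"].items()
    )


def _marker_from_config(name: str, cfg: dict) -> CAPSMarker:
    enzymes = tuple(ENZYMES[e] if e in ENZYMES else EnzymeSpec(**e) for e in cfg["enzymes"])
    gel = GelModel(**cfg["gel"]) if "gel" in cfg else GelModel()
    alleles = {
        a: MarkerAllele(a, spec["length"], {e: tuple(c) for e, c in spec["cuts"].items()})
        for a, spec in cfg["alleles"].items()
    }
    primers = tuple(cfg["primers"]) if "primers" in cfg else None
    return CAPSMarker(name, enzymes, alleles, primers, gel)


@lru_cache(maxsize=None)
def load_markers(path: str | None = None) -> dict[str, CAPSMarker]:
    """Marker fixtures from a JSON config (packaged set by default)."""
    if path is None:
        raw = _read_packaged("markers.json")
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return {name: _marker_from_config(name, cfg) for name, cfg in raw.items()}


def its_marker() -> CAPSMarker:
    return load_markers()["ITS"]


def prs_markers() -> dict[str, CAPSMarker]:
    return {k: v for k, v in load_markers().items() if k != "ITS"}


def build_synthetic_amplicon(length: int, planted: dict[str, list[tuple[int, str]]],
                             seed: int = 0) -> str:
    """A synthetic amplicon whose scanned cut positions equal a target cut map.

    ``planted`` maps enzyme name -> list of (cut_coordinate, strand).  The
    background is random but rejected/patched wherever it would create a
    spurious recognition site for any of the listed enzymes.
    """
    from .caps import find_sites  # local import to avoid cycle confusion

    enzymes = [ENZYMES[e] for e in planted]
    rng = random.Random(seed)
    site_regions: list[tuple[int, int, str]] = []  # 0-based [start, end), planted text
    for ename, cuts in planted.items():
        enz = ENZYMES[ename]
        L = len(enz.recognition)
        rec = "".join(_concrete_base(c, rng) for c in enz.recognition)
        from Bio.Seq import reverse_complement
        for cut, strand in cuts:
            if strand == "+":
                start = cut - L - enz.cut_offset_top  # pos = cut - L + 1 - offset, 0-based
                text = rec
            else:
                start = cut + enz.cut_offset_top  # pos - 1 = cut + offset, 0-based start
                text = reverse_complement(rec)
            if start < 0 or start + L > length:
                raise ValueError(f"{ename} cut {cut} cannot be planted inside the amplicon")
            site_regions.append((start, start + L, text))

    for _ in range(200):
        seq = [rng.choice("ACGT") for _ in range(length)]
        for start, end, text in site_regions:
            seq[start:end] = list(text)
        s = "".join(seq)
        expected = {(start + 1) for start, _, _ in site_regions}
        spurious = False
        for enz in enzymes:
            for pos, _strand in find_sites(s, enz):
                if pos not in expected:
                    spurious = True
        if not spurious:
            return s
    raise RuntimeError("could not build a clean synthetic amplicon")


def _concrete_base(code: str, rng: random.Random) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values
    return rng.choice(ambiguous_dna_values[code.upper()])
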