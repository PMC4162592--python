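"""Readers and writers: FASTA, dot-bracket, CT, probability and melting text.

All text outputs are deterministic: fixed column orders, 1-based
coordinates, probabilities to 4 decimals, free energies to 2 decimals,
temperatures to 2 decimals.  Writing the parse of a written file
reproduces it byte-identically.
"""

from __future__ import annotations

import io as _io
import os

import numpy as np

from rnamelt.sequence import RnaSequence, SequenceError
from rnamelt.structures import SecondaryStructure, helix_runs, runs_cross
from rnamelt.thermal import MeltingCurve

# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_sequence(source) -> RnaSequence:
    """Read a sequence from a path, FASTA text, or plain sequence text.

    Single-record FASTA only; T is normalized to U and case is folded.
    """
    text = None
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)):
        s = os.fspath(source)
        if not s.lstrip().startswith(">") and "\n" not in s and os.path.exists(s):
            with open(s) as fh:
                text = fh.read()
        else:
            text = s
    else:
        raise TypeError(f"cannot read a sequence from {type(source)!r}")
    text = text.strip()
    if text.startswith(">"):
        from Bio import SeqIO

        records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
        if len(records) != 1:
            raise SequenceError(f"expected a single FASTA record, found {len(records)}")
        return RnaSequence.parse(str(records[0].seq))
    return RnaSequence.parse(text)


def write_fasta(seq: RnaSequence, name: str = "seq") -> str:
    return f">{name}\n{seq}\n"


# ---------------------------------------------------------------------------
# structures: dot-bracket and CT
# ---------------------------------------------------------------------------

_OPENS = "([{"
_CLOSES = ")]}"


def structure_to_dotbracket(n: int, s: SecondaryStructure) -> str:
    """Dot-bracket with pseudoknot layers rendered ( ), then [ ], then { }."""
    layers: list[list] = []
    for pair in sorted(s.pairs):
        for layer in layers:
            if not any(runs_cross((*pair, 0), (*p, 0)) for p in layer):
                layer.append(pair)
                break
        else:
            layers.append([pair])
    if len(layers) > len(_OPENS):
        raise ValueError("structure needs more than 3 crossing layers")
    out = ["."] * n
    for d, layer in enumerate(layers):
        for (i, j) in layer:
            out[i] = _OPENS[d]
            out[j] = _CLOSES[d]
    return "".join(out)


def parse_dotbracket(text: str, validate_runs: bool = True) -> SecondaryStructure:
    """Parse dot-bracket text with up to three bracket layers ( ) [ ] { }."""
    stacks: dict[int, list] = {0: [], 1: [], 2: []}
    pairs = []
    for i, c in enumerate(text.strip()):
        if c == ".":
            continue
        if c in _OPENS:
            stacks[_OPENS.index(c)].append(i)
        elif c in _CLOSES:
            d = _CLOSES.index(c)
            if not stacks[d]:
                raise ValueError(f"unbalanced {c!r} at position {i + 1}")
            pairs.append((stacks[d].pop(), i))
        else:
            raise ValueError(f"unexpected character {c!r} at position {i + 1}")
    for d, st in stacks.items():
        if st:
            raise ValueError(f"unclosed {_OPENS[d]!r} at position {st[-1] + 1}")
    return SecondaryStructure(pairs, validate_runs=validate_runs)


def write_ct(seq: RnaSequence, s: SecondaryStructure, title: str = "structure") -> str:
    """Connectivity-table text (1-based, standard 6-column layout)."""
    n = len(seq)
    partner = s.partner()
    lines = [f"{n}\t{title}"]
    for i in range(n):
        j = partner.get(i, -1) + 1
        lines.append(f"{i + 1}\t{seq[i]}\t{i}\t{i + 2 if i + 1 < n else 0}\t{j}\t{i + 1}")
    return "\n".join(lines) + "\n"


def read_ct(text: str, validate_runs: bool = True):
    """(RnaSequence, SecondaryStructure) from CT text."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    n = int(header[0])
    bases = []
    pairs = []
    for ln in lines[1 : n + 1]:
        cols = ln.split()
        idx, base, j = int(cols[0]), cols[1], int(cols[4])
        bases.append(base)
        if j > 0 and j > idx:
            pairs.append((idx - 1, j - 1))
    seq = RnaSequence.parse("".join(bases))
    return seq, SecondaryStructure(pairs, validate_runs=validate_runs)


# ---------------------------------------------------------------------------
# probabilities, helices, melting curves
# ---------------------------------------------------------------------------

#: probabilities below this are not listed
BPP_WRITE_FLOOR = 5e-5


def write_bpp(result, floor: float = BPP_WRITE_FLOOR) -> str:
    """Base-pair probabilities as '# i j P_ij' text (1-based, 4 decimals)."""
    n = len(result.seq)
    lines = ["# i\tj\tP_ij"]
    for i in range(n):
        for j in range(i + 1, n):
            p = result.bpp[i, j]
            if p >= floor:
                lines.append(f"{i + 1}\t{j + 1}\t{p:.4f}")
    return "\n".join(lines) + "\n"


def read_bpp(text: str) -> list:
    """[(i, j, P)] with 1-based indices from probability text."""
    out = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        i, j, p = ln.split("\t")
        out.append((int(i), int(j), float(p)))
    return out


def write_helices(helices) -> str:
    """Helix list as '# i j length P' text (outer pair, 1-based)."""
    lines = ["# i\tj\tlength\tP"]
    for h in helices:
        lines.append(f"{h.start_i + 1}\t{h.start_j + 1}\t{h.length}\t{h.probability:.4f}")
    return "\n".join(lines) + "\n"


def read_helices(text: str) -> list:
    out = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        i, j, k, p = ln.split("\t")
        out.append((int(i), int(j), int(k), float(p)))
    return out


def write_structures(result) -> str:
    """Dominant + alternative structures in dot-bracket, with levels."""
    n = len(result.seq)
    lines = [f"# sequence\t{result.seq}"]
    dom, prob = result.dominant if result.dominant else (SecondaryStructure(()), 0.0)
    lines.append(f"# dominant (pairs with P>0.5), probability {prob:.4f}")
    lines.append(structure_to_dotbracket(n, dom))
    for (s, level) in result.alternatives:
        lines.append(f"# alternative, probability {level:.4f}")
        lines.append(structure_to_dotbracket(n, s))
    return "\n".join(lines) + "\n"


def write_melting(curve: MeltingCurve) -> str:
    """Heat capacity as '# T_celsius C' text (interior grid points)."""
    lines = ["# T_celsius\tC_kcal_mol_K"]
    for t, c in zip(curve.inner_grid, curve.C):
        lines.append(f"{t:.2f}\t{c:.6f}")
    return "\n".join(lines) + "\n"


def write_lnq(curve: MeltingCurve) -> str:
    """Companion lnQ file: '# T_celsius lnQ'."""
    lines = ["# T_celsius\tlnQ"]
    for t, q in zip(curve.grid, curve.lnQ):
        lines.append(f"{t:.2f}\t{q:.6f}")
    return "\n".join(lines) + "\n"


def read_melting(text: str) -> tuple[np.ndarray, np.ndarray]:
    """(T, value) columns from melting or lnQ text."""
    ts, vs = [], []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        t, v = ln.split("\t")
        ts.append(float(t))
        vs.append(float(v))
    return np.array(ts), np.array(vs)


__all__ = [
    "read_sequence",
    "write_fasta",
    "structure_to_dotbracket",
    "parse_dotbracket",
    "write_ct",
    "read_ct",
    "write_bpp",
    "read_bpp",
    "write_helices",
    "read_helices",
    "write_structures",
    "write_melting",
    "write_lnq",
    "read_melting",
    "BPP_WRITE_FLOOR",
]
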