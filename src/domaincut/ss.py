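"""Secondary-structure input.

Cut positions must not fall inside regular secondary-structure elements
(α-helices and β-strands), so the parser needs a per-residue H/E/C string.
The string comes from external tools — STRIDE or DSSP output in structure
mode, a PSIPRED ``.ss2`` file in sequence mode, or a bare one-line H/E/C
string — reduced from 8 states to 3 with the CASP-standard table:
{H, G, I} → H, {E, B, b} → E, everything else → C.

When no file is supplied, :func:`all_coil` disables the constraint (with a
warning): every position is then a legal cut site.
"""

from __future__ import annotations

import warnings
from pathlib import Path

REDUCE_8_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E", "b": "E",
}


class SSFormatError(ValueError):
    """Unrecognized or malformed secondary-structure file."""


def reduce_code(code: str) -> str:
    """Map one 8-state code to the 3-letter alphabet (total: unknown → C)."""
    code = code.strip()
    return REDUCE_8_TO_3.get(code, "C")


def _reduce(codes: list[str]) -> str:
    return "".join(reduce_code(c) for c in codes)


def all_coil(length: int) -> str:
    """All-coil fallback; the SSE cut constraint is then inactive."""
    if length < 1:
        raise ValueError("length must be >= 1")
    warnings.warn(
        "no secondary structure supplied: every position is a legal cut site",
        stacklevel=2,
    )
    return "C" * length


def read_stride_or_dssp(path: str | Path) -> str:
    """Parse STRIDE (ASG records) or DSSP output into an H/E/C string."""
    path = Path(path)
    text = path.read_text()
    if "ASG " in text or text.lstrip().startswith("REM"):
        codes = [
            line[24] if len(line) > 24 else "C"
            for line in text.splitlines()
            if line.startswith("ASG")
        ]
        if codes:
            return _reduce(codes)
    if "  #  RESIDUE" in text:
        return _parse_dssp(text)
    raise SSFormatError(f"unrecognized secondary-structure format: {path}")


def _parse_dssp(text: str) -> str:
    lines = text.splitlines()
    start = next(
        i for i, line in enumerate(lines) if line.startswith("  #  RESIDUE")
    )
    codes = []
    for line in lines[start + 1:]:
        if len(line) < 17:
            continue
        if line[13] == "!":  # chain break marker, not a residue
            continue
        codes.append(line[16])
    if not codes:
        raise SSFormatError("DSSP file contains no residue records")
    return _reduce(codes)


def read_psipred_ss2(path: str | Path) -> str:
    """Parse a PSIPRED ``.ss2`` file (index, residue, state, 3 probabilities)."""
    path = Path(path)
    states = []
    expected = 1
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise SSFormatError(f"malformed ss2 line: {raw!r}")
        try:
            idx = int(fields[0])
        except ValueError as exc:
            raise SSFormatError(f"malformed ss2 line: {raw!r}") from exc
        if idx != expected:
            raise SSFormatError(
                f"non-contiguous ss2 indices: expected {expected}, got {idx}"
            )
        expected += 1
        state = fields[2]
        if state not in ("H", "E", "C"):
            raise SSFormatError(f"unexpected ss2 state {state!r}")
        states.append(state)
    if not states:
        raise SSFormatError(f"empty ss2 file: {path}")
    return "".join(states)


def read_ss_string(path: str | Path) -> str:
    """Read a bare one-line H/E/C string file."""
    text = Path(path).read_text().strip()
    if not text or any(c not in "HEC" for c in text):
        raise SSFormatError(f"not a bare H/E/C string: {path}")
    return text


def load_secondary_structure(path: str | Path, length: int) -> str:
    """Dispatch on content: STRIDE/DSSP, ss2, or bare string; check length."""
    path = Path(path)
    text = path.read_text()
    stripped = text.strip()
    if not stripped:
        raise SSFormatError(f"empty secondary-structure file: {path}")
    if "ASG " in text or "  #  RESIDUE" in text or stripped.startswith("REM"):
        ss = read_stride_or_dssp(path)
    elif "\n" not in stripped and all(c in "HEC" for c in stripped):
        ss = stripped
    else:
        ss = read_psipred_ss2(path)
    if len(ss) != length:
        raise ValueError(
            f"secondary-structure length {len(ss)} does not match chain length {length}"
        )
    return ss
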