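"""Original Metaphone phonetic encoding (Lawrence Philips, 1990).

Maps similar-sounding English names to equal consonant-sound codes, e.g.
``smith`` and ``smyth`` both encode to ``SM0``.  The encoder is pure: the
same input always yields the same code, and the empty string encodes to the
empty code.  Input is expected to be a normalized lowercase a-z string;
other characters are dropped first.

The transformation rules implemented here are the published original-
Metaphone rules (16 consonant symbols ``B X S K J T F H L M N P R 0 W Y``,
where ``0`` is the *th* sound and ``X`` the *sh* sound): vowels are kept
only word-initially, doubled letters collapse (except ``c``), and the
context-sensitive consonant mappings below apply.  Double Metaphone is
deliberately not implemented; the encoder hook in
:class:`~linkclust.distances.DistanceSpec` keeps it pluggable.
"""

from __future__ import annotations

import re

__all__ = ["metaphone_encode"]

_VOWELS = "aeiou"
_CLEAN = re.compile(r"[^a-z]")


def metaphone_encode(s: str) -> str:
    """Return the Metaphone code of ``s`` (uppercase, possibly empty)."""
    s = _CLEAN.sub("", s.lower())
    if not s:
        return ""

    # Word-initial exceptions.
    if s[:2] in ("ae", "gn", "kn", "pn", "wr"):
        s = s[1:]
    elif s[0] == "x":
        s = "s" + s[1:]
    elif s[:2] == "wh":
        s = "w" + s[2:]

    out: list[str] = []
    n = len(s)
    i = 0
    while i < n:
        c = s[i]
        # Doubled letters collapse, except c (as in "accept").
        if c != "c" and i > 0 and s[i - 1] == c:
            i += 1
            continue
        nxt = s[i + 1] if i + 1 < n else ""
        nxt2 = s[i + 2] if i + 2 < n else ""
        prev = s[i - 1] if i > 0 else ""

        if c in _VOWELS:
            if i == 0:
                out.append(c.upper())
            i += 1
        elif c == "b":
            # Silent in terminal -mb ("dumb").
            if not (i == n - 1 and prev == "m"):
                out.append("B")
            i += 1
        elif c == "c":
            if nxt == "i" and nxt2 == "a":  # -cia-
                out.append("X")
                i += 1
            elif nxt == "h":
                out.append("K" if prev == "s" else "X")  # sch- vs ch-
                i += 2
            elif nxt in "iey":
                if prev != "s":  # silent in -sci-, -sce-, -scy-
                    out.append("S")
                i += 1
            else:
                out.append("K")
                i += 1
        elif c == "d":
            if nxt == "g" and nxt2 in "iey":  # -dge-, -dgy-, -dgi-
                out.append("J")
                i += 2
            else:
                out.append("T")
                i += 1
        elif c == "f":
            out.append("F")
            i += 1
        elif c == "g":
            if nxt == "h":
                if i + 2 < n and nxt2 not in _VOWELS:
                    i += 2  # silent gh as in "night"
                else:
                    out.append("K")
                    i += 2
            elif nxt == "n" and (i + 2 == n or s[i + 1 :] == "ned"):
                i += 1  # silent in -gn, -gned
            elif nxt in "iey":
                out.append("J")
                i += 1
            else:
                out.append("K")
                i += 1
        elif c == "h":
            # Silent after a vowel when no vowel follows.
            if prev in _VOWELS and nxt not in _VOWELS:
                i += 1
            else:
                out.append("H")
                i += 1
        elif c == "j":
            out.append("J")
            i += 1
        elif c == "k":
            if prev != "c":
                out.append("K")
            i += 1
        elif c in "lmnr":
            out.append(c.upper())
            i += 1
        elif c == "p":
            if nxt == "h":
                out.append("F")
                i += 2
            else:
                out.append("P")
                i += 1
        elif c == "q":
            out.append("K")
            i += 1
        elif c == "s":
            if nxt == "h":
                out.append("X")
                i += 2
            elif nxt == "i" and nxt2 in ("o", "a"):  # -sio-, -sia-
                out.append("X")
                i += 1
            else:
                out.append("S")
                i += 1
        elif c == "t":
            if nxt == "i" and nxt2 in ("o", "a"):  # -tio-, -tia-
                out.append("X")
                i += 1
            elif nxt == "h":
                out.append("0")
                i += 2
            elif nxt == "c" and nxt2 == "h":
                i += 1  # silent in -tch-
            else:
                out.append("T")
                i += 1
        elif c == "v":
            out.append("F")
            i += 1
        elif c == "w":
            if nxt in _VOWELS:
                out.append("W")
            i += 1
        elif c == "x":
            out.append("KS")
            i += 1
        elif c == "y":
            if nxt in _VOWELS:
                out.append("Y")
            i += 1
        elif c == "z":
            out.append("S")
            i += 1
        else:  # pragma: no cover - input is restricted to a-z
            i += 1
    return "".join(out)
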