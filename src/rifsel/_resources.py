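"""Access to packaged resource files (stop words, homonyms, heading map...)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def _lines(name: str) -> list[str]:
    text = resources.files("rifsel.resources").joinpath(name).read_text(encoding="utf-8")
    out = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.lstrip().startswith("#"):
            continue
        out.append(line)
    return out


@lru_cache(maxsize=None)
def stopwords(name: str = "english-basic") -> frozenset[str]:
    """Named stop-word list; only ``english-basic`` ships with the package."""
    if name != "english-basic":
        raise KeyError(f"unknown stopword list: {name!r}")
    return frozenset(w.lower() for w in _lines("stopwords.txt"))


@lru_cache(maxsize=None)
def homonyms() -> frozenset[str]:
    """Gene surface forms requiring case-sensitive matching."""
    return frozenset(_lines("homonyms.txt"))


@lru_cache(maxsize=None)
def heading_map() -> dict[str, str]:
    """Structured-abstract heading -> canonical discourse label."""
    out: dict[str, str] = {}
    for line in _lines("heading_map.tsv"):
        heading, label = line.split("\t")
        out[heading.strip().upper()] = label.strip()
    return out


@lru_cache(maxsize=None)
def nonhuman_mesh() -> frozenset[str]:
    """MeSH descriptors denoting non-human organisms."""
    return frozenset(_lines("nonhuman_mesh.txt"))
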