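"""Preferred-term to system-organ-class mapping.

MedDRA is multiaxial: a preferred term (PT) may be linked to several system
organ classes (SOCs), but exactly one of them is its *primary* SOC.  All
SOC-level counting in this package goes through the primary SOC only, so a
reaction is never counted in two organ classes.

The dictionary itself is licensed content and therefore never shipped: the
user supplies a delimited text file (one PT per line), or the synthetic
generator emits a complete synthetic dictionary for testing.

File format (``|``-separated, ``#`` comments)::

    PNEUMONIA | Infections and infestations
    CARDIAC FAILURE | Cardiac disorders | Vascular disorders; Investigations

Column three, when present, lists secondary SOCs separated by ``;``.  They
are retained for inspection but take no part in counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DictionaryError
from .faers_io import normalize_pt

#: Sentinel SOC returned for PTs absent from the dictionary.
UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class PtSocMap:
    """Immutable PT -> (primary SOC, secondary SOCs) dictionary."""

    primary: Mapping[str, str]
    secondary: Mapping[str, frozenset[str]] = field(default_factory=dict)
    version_label: str = "synthetic"

    def __post_init__(self) -> None:
        for pt, socs in self.secondary.items():
            prim = self.primary.get(pt)
            if prim is not None and prim in socs:
                raise DictionaryError(
                    f"PT {pt!r}: primary SOC {prim!r} also listed as secondary")

    @property
    def socs(self) -> frozenset[str]:
        return frozenset(self.primary.values())

    def __len__(self) -> int:
        return len(self.primary)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.primary


def build_pt_soc_map(rows: Iterable[tuple[str, str, Iterable[str]]],
                     version_label: str = "synthetic") -> PtSocMap:
    """Assemble a map from (pt, primary_soc, secondary_socs) rows.

    Duplicate rows with identical content collapse silently; a PT listed
    with two different primary SOCs is a dictionary error.
    """
    primary: dict[str, str] = {}
    secondary: dict[str, frozenset[str]] = {}
    for pt, prim, secs in rows:
        pt = normalize_pt(pt)
        prim = str(prim).strip()
        secs = frozenset(s.strip() for s in secs if str(s).strip())
        if pt in primary:
            if primary[pt] != prim:
                raise DictionaryError(
                    f"PT {pt!r} listed with two primary SOCs: "
                    f"{primary[pt]!r} and {prim!r}")
            secondary[pt] = secondary.get(pt, frozenset()) | secs
        else:
            primary[pt] = prim
            secondary[pt] = secs
    return PtSocMap(primary=primary, secondary=secondary, version_label=version_label)


def load_pt_soc_map(path: str | Path, version_label: str | None = None) -> PtSocMap:
    """Load a PT->SOC dictionary from its delimited text file."""
    path = Path(path)
    if not path.exists():
        raise DictionaryError(f"PT->SOC dictionary not found: {path}")
    rows = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("|")]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise DictionaryError(f"{path}:{lineno}: expected 'PT | primary SOC [| secondary;...]'")
        secs = parts[2].split(";") if len(parts) > 2 else []
        rows.append((parts[0], parts[1], secs))
    return build_pt_soc_map(rows, version_label or path.stem)


def write_pt_soc_map(mapping: PtSocMap, path: str | Path) -> None:
    lines = [f"# PT -> primary SOC dictionary ({mapping.version_label})"]
    for pt in sorted(mapping.primary):
        secs = ";".join(sorted(mapping.secondary.get(pt, ())))
        line = f"{pt} | {mapping.primary[pt]}"
        if secs:
            line += f" | {secs}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def map_pt(pt: str, mapping: PtSocMap) -> str:
    """Primary SOC of ``pt``, or :data:`UNMAPPED` when absent.

    Unmapped PTs stay in PT-level analyses and are merely counted; they
    contribute to no SOC-level table.
    """
    return mapping.primary.get(normalize_pt(pt), UNMAPPED)
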