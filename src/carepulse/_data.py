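"""Loaders for the small data files shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("carepulse") / "data" / name)


def read_word_list(path) -> list[str]:
    """Read a one-entry-per-line word file; '#'-comments and blanks ignored."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line)
    return words
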