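"""Run provenance: every CLI command records the resolved parameters it
ran with, so any output can be regenerated bit-identically."""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path

from . import __version__


def provenance_record(command: str, params: dict) -> dict:
    return {
        "tool": "mirrorface",
        "version": __version__,
        "command": command,
        "params": params,
        "python": sys.version.split()[0],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_provenance(output_path: str | Path, command: str, params: dict) -> Path:
    """Write ``<output>.provenance.json`` next to an output artifact."""
    out = Path(output_path)
    prov_path = out.with_name(out.name + ".provenance.json")
    prov_path.write_text(json.dumps(provenance_record(command, params), indent=1))
    return prov_path
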