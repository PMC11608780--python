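"""Clean the raw recordings: median smoothing + 1-Hz low-pass for skin
conductance; artifact correction and 32-Hz resampling for inter-beat
intervals. Writes cleaned CSVs plus a per-participant QC report
(beats flagged/interpolated) under results/preprocessed/.
"""

import argparse
from pathlib import Path

import pandas as pd

from physiosync import PreprocessConfig, StudyDataset, correct_ibi, ibi_to_series, preprocess_sc
from physiosync.signal_io import write_recording


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/preprocessed"))
    args = ap.parse_args()

    ds = StudyDataset.from_dir(args.dataset)
    cfg = PreprocessConfig()
    (args.out_dir / "sc").mkdir(parents=True, exist_ok=True)
    (args.out_dir / "hr").mkdir(parents=True, exist_ok=True)
    qc = []
    for pid in ds.participants:
        clean = preprocess_sc(ds.sc_recordings[pid], cfg)
        write_recording(clean, args.out_dir / "sc" / f"{pid}.csv")
        corrected, flags = correct_ibi(ds.hr_ibi[pid].intervals_ms, cfg,
                                       return_flags=True)
        hr = ibi_to_series(corrected, cfg.ibi_resample_hz, pid)
        write_recording(hr, args.out_dir / "hr" / f"{pid}.csv")
        qc.append({"participant": pid, "n_beats": flags.size,
                   "n_flagged": int(flags.sum()),
                   "pct_flagged": round(100 * flags.mean(), 2)})
    qc_df = pd.DataFrame(qc)
    qc_df.to_csv(args.out_dir / "qc_report.csv", index=False)
    print(f"preprocessed {len(ds.participants)} participants -> {args.out_dir}")
    print(f"median flagged beats: {qc_df['n_flagged'].median():.0f} "
          f"({qc_df['pct_flagged'].median():.1f}%)")


if __name__ == "__main__":
    main()
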