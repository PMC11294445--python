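"""Genome summaries and deviation-from-average GC-skew tracks; localize the
skew sign flip and compare it with the planted replication origin."""

from pathlib import Path

import pandas as pd

from wolbkit import genome_stats, io_formats, simulate

SEED = 42
OUT = Path("results/genome_stats")
WINDOW, STEP = 4_000, 500


def main() -> None:
    ds = simulate.simulate_dataset(seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for strain, genome in sorted(ds.genomes.items()):
        summary = genome_stats.genome_summary(genome)
        track = genome_stats.windowed_profile(
            genome, metric="gc_skew", window=WINDOW, step=STEP, deviation=True
        )
        io_formats.write_track(OUT / f"{strain}.gcskew.tsv", track)
        flips = genome_stats.skew_sign_changes(track)
        origin = ds.truth.origin_position[strain]
        length = len(genome)
        nearest = min(
            min(abs(f - origin), length - abs(f - origin)) for f in flips
        )
        summary["skew_flip_error_bp"] = nearest
        rows.append(summary)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "genome_summary.tsv", sep="\t", index=False)

    print(table[["strain_id", "length_bp", "gc_percent", "skew_flip_error_bp"]]
          .to_string(index=False))
    worst = table["skew_flip_error_bp"].max()
    print(f"\nskew flip localized within {worst} bp of the planted origin "
          f"on every strain (window = {WINDOW} bp)")
    print(f"wrote per-strain tracks and {OUT}/genome_summary.tsv")


if __name__ == "__main__":
    main()
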