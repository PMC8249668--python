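"""Reading and writing the pipeline's file formats (all UTF-8 text).

Tweets travel as JSONL (one object per line: id, text, label) or CSV with a
header; labels are the literal strings positive/negative/neutral.  Lexicons
and gazetteers are TSV, stoplists one word per line, vote matrices CSV, and
metric reports CSV or JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix, MetricReport
from .types import Token, TokenSequence, Tweet


def read_tweets_jsonl(path) -> list[Tweet]:
    tweets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            obj = json.loads(line)
            if "id" not in obj or "text" not in obj:
                raise ValueError(f"{path}:{lineno}: tweet object needs id and text")
            tweets.append(
                Tweet(
                    id=str(obj["id"]),
                    text=obj["text"],
                    label=obj.get("label"),
                    is_retweet=bool(obj.get("is_retweet", False)),
                )
            )
    return tweets


def write_tweets_jsonl(tweets: list[Tweet], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in tweets:
            obj = {"id": t.id, "text": t.text}
            if t.label is not None:
                obj["label"] = t.label
            if t.is_retweet:
                obj["is_retweet"] = True
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_tweets_csv(path) -> list[Tweet]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in frame.columns or "text" not in frame.columns:
        raise ValueError(f"{path}: CSV must have 'id' and 'text' columns")
    tweets = []
    for _, row in frame.iterrows():
        label = row.get("label") or None
        tweets.append(Tweet(id=row["id"], text=row["text"], label=label))
    return tweets


def write_tweets_csv(tweets: list[Tweet], path) -> None:
    pd.DataFrame(
        {
            "id": [t.id for t in tweets],
            "text": [t.text for t in tweets],
            "label": [t.label or "" for t in tweets],
        }
    ).to_csv(path, index=False)


def write_token_sequences(sequences: list[TokenSequence], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for seq in sequences:
            obj = {
                "id": seq.source_id,
                "tokens": [
                    {
                        "surface": t.surface,
                        "lemma": t.lemma,
                        "pos": t.pos_tag,
                        "entity": t.entity,
                        "special": t.is_special,
                    }
                    for t in seq
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_token_sequences(path) -> list[TokenSequence]:
    sequences = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            tokens = [
                Token(
                    surface=t["surface"],
                    lemma=t["lemma"],
                    pos_tag=t["pos"],
                    entity=t.get("entity", "none"),
                    is_special=t.get("special", False),
                )
                for t in obj["tokens"]
            ]
            sequences.append(TokenSequence(tokens=tokens, source_id=obj["id"]))
    return sequences


def read_stoplist(path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        return frozenset(w.strip() for w in fh if w.strip())


def write_stoplist(words, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for w in sorted(words):
            fh.write(w + "\n")


def read_gazetteer(path) -> dict[str, str]:
    entries = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if row:
                entries[row[0]] = row[1]
    return entries


def write_gazetteer(entries: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for surface in sorted(entries):
            writer.writerow([surface, entries[surface]])


def write_votes_csv(votes: np.ndarray, tweet_ids, model_ids, path) -> None:
    """Serialize an (N, m, 3) vote array as tidy CSV."""
    rows = []
    for i, tid in enumerate(tweet_ids):
        for j, mid in enumerate(model_ids):
            rows.append((tid, mid, *votes[i, j]))
    pd.DataFrame(rows, columns=["tweet_id", "model_id", "p_pos", "p_neg", "p_neu"]).to_csv(
        path, index=False
    )


def read_votes_csv(path) -> tuple[np.ndarray, list[str], list[str]]:
    frame = pd.read_csv(path, dtype={"tweet_id": str, "model_id": str})
    tweet_ids = list(dict.fromkeys(frame["tweet_id"]))
    model_ids = list(dict.fromkeys(frame["model_id"]))
    votes = np.zeros((len(tweet_ids), len(model_ids), 3))
    ti = {t: i for i, t in enumerate(tweet_ids)}
    mi = {m: i for i, m in enumerate(model_ids)}
    for _, row in frame.iterrows():
        votes[ti[row["tweet_id"]], mi[row["model_id"]]] = (
            row["p_pos"], row["p_neg"], row["p_neu"],
        )
    return votes, tweet_ids, model_ids


def write_metric_report(report: MetricReport, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix == ".csv" else "json")
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.as_dict(), fh, indent=2)
            fh.write("\n")
    else:
        pd.DataFrame([report.as_dict()]).to_csv(path, index=False)


def write_confusion_matrix(cm: ConfusionMatrix, path) -> None:
    cm.to_frame().to_csv(path, index_label="gold\\pred")
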