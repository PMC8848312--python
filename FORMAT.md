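# mbgcpy archive format (version 1)

A single-file container holding the independently compressed streams of an
encoded genome collection. All multi-byte integers are unsigned LEB128
varints (7 data bits per byte, little-endian groups, high bit = continue).
This format is **not** compatible with the original MBGC `.mbgc` files.

## Layout

| field            | size      | content                                      |
|------------------|-----------|----------------------------------------------|
| magic            | 7 bytes   | `4D 42 47 43 70 79 00` (`MBGCpy\0`)          |
| version          | 1 byte    | `01`                                         |
| parameter block  | varints   | see below                                    |
| stream count     | varint    | `10` in version 1                            |
| stream directory | per entry | id (u8), backend id (u8), raw size (varint), compressed size (varint) |
| payloads         | bytes     | compressed streams concatenated in directory order |

## Parameter block

Ten varints in order: `mode` (0 = default, 1 = max), `k`, `stride`, `m`,
`u`, `table_bits`, `ref_limit`, `rc_enabled` (0/1), `swallow` (0/1),
`backend_level`. These echo the encoder configuration so the decoder needs
no external input.

## Streams

| id | name           | encoding                                              |
|----|----------------|-------------------------------------------------------|
| 0  | filenames      | UTF-8 relative paths, NUL-separated                   |
| 1  | contig_counts  | varint per file                                       |
| 2  | headers        | raw header lines (no `>`/EOL), NUL-separated          |
| 3  | token_counts   | varint per contig                                     |
| 4  | token_kinds    | 1 bit per token (1 = match, 0 = literal), packed little-endian |
| 5  | offsets        | varint per match token (0-based REF position)         |
| 6  | lengths        | varint per match token                                |
| 7  | literal_lens   | varint per literal run                                |
| 8  | literal_bytes  | concatenated literal symbols                          |
| 9  | appended_flags | 1 bit per contig (1 = contig extended REF), packed little-endian |

Counts compose: the number of files is the length of `contig_counts`, the
number of contigs is its sum, the number of tokens the sum of
`token_counts`, the number of matches the popcount of `token_kinds`.
Headers and file names therefore must not contain NUL bytes.

## Back-end

Backend id 1 = LZMA (`.xz` container, preset = `backend_level`; 6 in the
default mode, 9 in max mode). Every stream records its own backend id so
alternates can be added without a version bump.

## Decoding contract

In default mode the first file's contigs travel exclusively through the
literal streams; after reconstructing them the decoder initialises REF with
their concatenation followed by its reverse complement. Every other contig
is rebuilt by replaying its tokens against the current REF, after which REF
is extended (contig + reverse complement, circular overwrite past
`ref_limit`) iff the contig's `appended` flag is set. In max mode the same
replay starts from an empty REF with no special first file.
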