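"""Encode a percent frame the way the firmware does, then decode it back.

Each 0-100 pressure value travels as the single ASCII byte with that
codepoint (40 goes out as '('), inside an 18-byte frame: one header byte
naming the foot, 16 payload bytes, one newline delimiter.
"""

from baropod import PercentVector, bits_view, decode_stream, encode_frame

vector = PercentVector(
    timestamp_ms=0,
    values=(40, 65, 84, 0, 12, 7, 99, 100, 3, 55, 40, 23, 81, 10, 0, 47),
    foot="left",
)
frame = encode_frame(vector)
print(f"frame length: {len(frame)} bytes")
print(f"payload byte for value 40: 0x{frame[1]:02X} -> {chr(frame[1])!r}")
print(f"payload as characters: {frame[1:17]!r}")
print(f"bit view of b'AT':     {bits_view(b'AT')}")

decoded = decode_stream(frame)
print(f"decoded values match: {decoded.frames[0].values == vector.values}")
print()
print("The codec is lossless on the 0-100 range; values 101-255 fit the")
print("byte but are flagged by the decoder (or rejected in strict mode).")
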