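illustrative: true
scenarios:
- region: Bonn
  species: inachis_io
  x: 0.4
  a: 0.5
  z: 0.1
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 10.0
  D: 2.0
  q: 0.1
- region: Bonn
  species: vanessa_atalanta
  x: 0.4
  a: 0.5
  z: 0.1
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 10.0
  D: 2.0
  q: 0.1
- region: Bonn
  species: plutella_xylostella
  x: 0.5
  a: 0.5
  z: 0.1
  v: 0.8
  y: 0.5
  e: 0.0
  f: 0.5
  C: 10.0
  D: 2.0
  q: 0.1
- region: Oderbruch
  species: inachis_io
  x: 0.4
  a: 0.5
  z: 0.2
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 30.0
  D: 2.0
  q: 0.2
- region: Oderbruch
  species: vanessa_atalanta
  x: 0.4
  a: 0.5
  z: 0.2
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 30.0
  D: 2.0
  q: 0.2
- region: Oderbruch
  species: plutella_xylostella
  x: 0.5
  a: 0.5
  z: 0.2
  v: 0.8
  y: 0.5
  e: 0.0
  f: 0.5
  C: 30.0
  D: 2.0
  q: 0.2
- region: Aachen
  species: inachis_io
  x: 0.4
  a: 0.5
  z: 0.15
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 8.0
  D: 1.5
  q: 0.1
- region: Aachen
  species: vanessa_atalanta
  x: 0.4
  a: 0.5
  z: 0.15
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 8.0
  D: 1.5
  q: 0.1
- region: Aachen
  species: plutella_xylostella
  x: 0.5
  a: 0.5
  z: 0.15
  v: 0.8
  y: 0.5
  e: 0.0
  f: 0.5
  C: 8.0
  D: 1.5
  q: 0.1
- region: Berkatal
  species: inachis_io
  x: 0.4
  a: 0.5
  z: 0.25
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 5.0
  D: 2.0
  q: 0.0
- region: Berkatal
  species: vanessa_atalanta
  x: 0.4
  a: 0.5
  z: 0.25
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 5.0
  D: 2.0
  q: 0.0
- region: Berkatal
  species: plutella_xylostella
  x: 0.5
  a: 0.5
  z: 0.25
  v: 0.8
  y: 0.5
  e: 0.0
  f: 0.5
  C: 5.0
  D: 2.0
  q: 0.0
- region: Grebbin
  species: inachis_io
  x: 0.4
  a: 0.5
  z: 0.5
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 40.0
  D: 1.0
  q: 0.3
- region: Grebbin
  species: vanessa_atalanta
  x: 0.4
  a: 0.5
  z: 0.5
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 40.0
  D: 1.0
  q: 0.3
- region: Grebbin
  species: plutella_xylostella
  x: 0.5
  a: 0.5
  z: 0.5
  v: 0.8
  y: 0.5
  e: 0.0
  f: 0.5
  C: 40.0
  D: 1.0
  q: 0.3
- region: Upper Rhine Valley
  species: inachis_io
  x: 0.4
  a: 0.5
  z: 0.7
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 15.0
  D: 1.0
  q: 0.3
- region: Upper Rhine Valley
  species: vanessa_atalanta
  x: 0.4
  a: 0.5
  z: 0.7
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 15.0
  D: 1.0
  q: 0.3
- region: Upper Rhine Valley
  species: plutella_xylostella
  x: 0.5
  a: 0.5
  z: 0.7
  v: 0.8
  y: 0.5
  e: 0.5
  f: 0.5
  C: 15.0
  D: 1.0
  q: 0.3
- region: Tolna County
  species: inachis_io
  x: 0.4
  a: 0.5
  z: 0.2
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 58.0
  D: 4.5
  q: 0.1
- region: Tolna County
  species: vanessa_atalanta
  x: 0.2
  a: 0.5
  z: 0.2
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 58.0
  D: 4.5
  q: 0.1
- region: Tolna County
  species: plutella_xylostella
  x: 0.5
  a: 0.5
  z: 0.2
  v: 0.8
  y: 0.5
  e: 0.0
  f: 0.5
  C: 58.0
  D: 4.5
  q: 0.1
- region: Po Valley (central)
  species: inachis_io
  x: 0.4
  a: 0.5
  z: 0.6
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 12.0
  D: 2.0
  q: 0.2
- region: Po Valley (central)
  species: vanessa_atalanta
  x: 0.4
  a: 0.5
  z: 0.6
  v: 0.8
  y: 0.23
  e: 0.0
  f: 0.5
  C: 12.0
  D: 2.0
  q: 0.2
- region: Po Valley (central)
  species: plutella_xylostella
  x: 0.5
  a: 0.5
  z: 0.6
  v: 0.8
  y: 0.5
  e: 0.0
  f: 0.5
  C: 12.0
  D: 2.0
  q: 0.2
- region: Po Valley (coastal)
  species: plutella_xylostella
  x: 0.5
  a: 0.5
  z: 0.3
  v: 0.8
  y: 0.5
  e: 0.0
  f: 0.5
  C: 10.0
  D: 2.0
  q: 0.2
- region: Madrid
  species: inachis_io
  x: 0.2
  a: 0.1
  z: 0.024
  v: 0.035
  y: 0.0
  e: 0.0
  f: 0.001
  C: 20.0
  D: 1.0
  q: 0.5
- region: Madrid
  species: vanessa_atalanta
  x: 0.2
  a: 0.1
  z: 0.024
  v: 0.035
  y: 0.0
  e: 0.0
  f: 0.001
  C: 20.0
  D: 1.0
  q: 0.5
- region: Madrid
  species: plutella_xylostella
  x: 0.1
  a: 0.1
  z: 0.024
  v: 0.035
  y: 0.1
  e: 0.0
  f: 0.001
  C: 20.0
  D: 1.0
  q: 0.5
- region: Ebro Valley
  species: inachis_io
  x: 0.2
  a: 0.1
  z: 0.3
  v: 0.65
  y: 0.0
  e: 0.0
  f: 0.001
  C: 5.0
  D: 1.0
  q: 0.5
- region: Ebro Valley
  species: vanessa_atalanta
  x: 0.2
  a: 0.1
  z: 0.3
  v: 0.65
  y: 0.0
  e: 0.0
  f: 0.001
  C: 5.0
  D: 1.0
  q: 0.5
- region: Ebro Valley
  species: plutella_xylostella
  x: 0.1
  a: 0.1
  z: 0.3
  v: 0.65
  y: 0.1
  e: 0.0
  f: 0.001
  C: 5.0
  D: 1.0
  q: 0.5
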