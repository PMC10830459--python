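{
  "elapsed_s": 244.4,
  "equilibrium_years": 16,
  "spinup_climate_years": [
    1850,
    1857,
    1856,
    1854,
    1854,
    1858,
    1850,
    1856,
    1852,
    1850,
    1855,
    1859,
    1857,
    1857,
    1857,
    1857,
    1855,
    1851,
    1858,
    1854,
    1855,
    1853,
    1851,
    1859,
    1857,
    1856,
    1854,
    1858,
    1855,
    1854
  ],
  "decadal_total_GgN": {
    "1850": 0.06991523983719666,
    "1860": 0.07574977649823784,
    "1870": 0.08182187294724554,
    "1880": 0.09568178802767417,
    "1890": 0.10795339824148689,
    "1900": 0.12367922459575509,
    "1910": 0.14147876066420334,
    "1920": 0.16683745146543696,
    "1930": 0.20299677640163485,
    "1940": 0.2345324844001489,
    "1950": 0.3217120518286472,
    "1960": 0.5316612010767612,
    "1970": 0.636680797560655,
    "1980": 0.7629677053913689,
    "1990": 0.8715437758186899,
    "2000": 0.9811556378866502,
    "2010": 1.0881408605570249
  },
  "decadal_lentic_GgN": {
    "1850": 0.03607106383282999,
    "1860": 0.037635418158836545,
    "1870": 0.03954008509363281,
    "1880": 0.0428546821301789,
    "1890": 0.04619279035982547,
    "1900": 0.05036057376669569,
    "1910": 0.05499205389694395,
    "1920": 0.06284794487974174,
    "1930": 0.07144706498543732,
    "1940": 0.07983834572185429,
    "1950": 0.13409171821097773,
    "1960": 0.2835589309294932,
    "1970": 0.33613233685909366,
    "1980": 0.3984360477082138,
    "1990": 0.453342142128449,
    "2000": 0.5069397374800749,
    "2010": 0.5590516680911664
  },
  "decadal_lake_GgN": {
    "1850": 0.03607106383282999,
    "1860": 0.037635418158836545,
    "1870": 0.03954008509363281,
    "1880": 0.0428546821301789,
    "1890": 0.04619279035982547,
    "1900": 0.05036057376669569,
    "1910": 0.0547481180378542,
    "1920": 0.06031416215364963,
    "1930": 0.0686066632938965,
    "1940": 0.07650087007237032,
    "1950": 0.08616688079144144,
    "1960": 0.1013309974641092,
    "1970": 0.11731081842685573,
    "1980": 0.13610679266692477,
    "1990": 0.15185522560264472,
    "2000": 0.16749155733516785,
    "2010": 0.18250355974220994
  }
}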