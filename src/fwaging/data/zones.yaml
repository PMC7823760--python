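# Region -> zone membership used by the zone aggregation stage.
# Edit freely; any region named in a scored panel must appear exactly once.
# The three flagship zone memberships are pre-filled; the remaining five
# zones group the other provinces by customary economic geography.
zones:
  Beijing-Tianjin-Hebei:
    - Beijing
    - Tianjin
    - Hebei
  Yangtze River Delta:
    - Shanghai
    - Jiangsu
    - Zhejiang
  Pearl River Delta:
    - Guangdong
  Northeast:
    - Liaoning
    - Jilin
    - Heilongjiang
  North and Central:
    - Shanxi
    - Inner Mongolia
    - Henan
    - Hubei
    - Hunan
    - Anhui
    - Jiangxi
  East Coast:
    - Shandong
    - Fujian
    - Hainan
    - Guangxi
  Southwest:
    - Chongqing
    - Sichuan
    - Guizhou
    - Yunnan
  Northwest:
    - Shaanxi
    - Gansu
    - Qinghai
    - Ningxia
    - Xinjiang
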