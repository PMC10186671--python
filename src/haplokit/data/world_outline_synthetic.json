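{
  "note": "Synthetic, hand-drawn schematic continent outlines (lon/lat polygons). Deliberately coarse; for orientation behind geo pies only, not a geographic reference.",
  "polygons": [
    [[-168,66],[-140,60],[-125,49],[-117,33],[-105,24],[-97,16],[-83,9],[-77,8],[-81,25],[-76,35],[-66,45],[-53,47],[-60,55],[-70,60],[-85,64],[-110,68],[-140,70],[-168,66]],
    [[-77,8],[-70,12],[-60,5],[-50,0],[-35,-8],[-40,-22],[-48,-28],[-58,-34],[-65,-41],[-71,-52],[-75,-50],[-72,-38],[-70,-18],[-77,-6],[-80,0],[-77,8]],
    [[-17,15],[-5,35],[10,37],[20,33],[32,31],[43,12],[51,12],[40,-2],[40,-15],[35,-22],[31,-30],[20,-35],[17,-29],[12,-18],[9,-1],[9,4],[-8,4],[-15,10],[-17,15]],
    [[-10,36],[-9,43],[-2,48],[0,51],[8,54],[12,56],[20,55],[28,60],[25,65],[30,70],[45,68],[60,69],[90,72],[110,73],[140,72],[160,69],[180,65],[178,64],[160,60],[142,54],[135,43],[122,40],[120,32],[110,21],[105,10],[103,2],[99,8],[92,21],[88,22],[80,15],[77,8],[72,20],[67,24],[57,25],[50,28],[48,30],[35,36],[27,36],[22,38],[18,40],[12,38],[3,43],[-10,36]],
    [[95,-1],[104,-3],[106,-6],[114,-8],[119,-9],[117,-1],[109,2],[101,2],[95,-1]],
    [[114,-22],[122,-18],[130,-12],[137,-12],[142,-11],[146,-19],[150,-22],[153,-28],[150,-37],[146,-39],[140,-38],[135,-35],[129,-32],[124,-33],[115,-34],[113,-26],[114,-22]],
    [[167,-46],[172,-41],[174,-38],[178,-37],[176,-41],[170,-46],[167,-46]],
    [[-24,64],[-15,66],[-13,65],[-18,63],[-24,64]],
    [[129,31],[132,34],[137,35],[141,38],[142,42],[145,44],[142,45],[140,40],[135,35],[130,33],[129,31]]
  ]
}
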